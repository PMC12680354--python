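"""Compacted transcriptome de Bruijn graph (T-DBG) index.

The index stores the reference transcriptome as a compacted, colored de
Bruijn graph at a fixed odd k (default 63).  Nodes are canonical k-mers,
collapsed into unitigs; a unitig is a maximal non-branching run of k-mers
that all share the same transcript compatibility class (TCC), so every
unitig maps to exactly one TCC.  Long k-mers keep the graph sparse and the
classes small, which is what makes pseudoalignment of noisy long reads
reliable: a k-mer that survives sequencing error intact is very likely to
identify its transcript(s) of origin uniquely.

An optional "distinguishing list" (d-list) of canonical k-mers drawn from
non-transcriptome sequence (e.g. intron flanks) acts as a set of negative
certificates: a read containing a d-listed k-mer is vetoed rather than
mapped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import networkx as nx

__all__ = [
    "TranscriptSet",
    "Unitig",
    "TDBGIndex",
    "GraphStats",
    "KmerHit",
    "reverse_complement",
    "canonical",
    "build_index",
    "lookup_kmer",
    "build_dlist",
    "graph_stats",
    "save_index",
    "load_index",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

INDEX_FORMAT_VERSION = 1
DEFAULT_K = 63
MIN_K = 15


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _validate_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{label}: invalid characters {sorted(bad)!r}")


@dataclass(frozen=True)
class TranscriptSet:
    """Ordered reference transcripts.

    The position of a record is its ordinal; ordinals define the
    tie-breaking order ("first occurring transcript") used downstream.
    """

    records: tuple  # tuple of (transcript_id, sequence)

    def __post_init__(self):
        ids = [tid for tid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate transcript ids")
        for tid, seq in self.records:
            _validate_sequence(seq, tid)

    @classmethod
    def from_pairs(cls, pairs: Iterable) -> "TranscriptSet":
        return cls(tuple((tid, seq.upper().replace("U", "T")) for tid, seq in pairs))

    @classmethod
    def from_fasta(cls, path) -> "TranscriptSet":
        from .seqio import parse_fasta

        return cls(tuple(parse_fasta(path)))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple:
        return tuple(tid for tid, _ in self.records)

    @property
    def lengths(self) -> tuple:
        return tuple(len(seq) for _, seq in self.records)

    def ordinal_of(self, transcript_id: str) -> int:
        return self.ids.index(transcript_id)


@dataclass(frozen=True)
class Unitig:
    """Maximal non-branching, single-TCC run of k-mers, stored as a sequence."""

    sequence: str
    tcc_id: int
    predecessors: frozenset
    successors: frozenset


class KmerHit(NamedTuple):
    unitig_id: int
    offset: int
    orientation: str  # "forward" if the query equals the stored canonical form
    tcc: tuple


@dataclass(frozen=True)
class GraphStats:
    k: int
    n_nodes: int
    n_edges: int
    largest_component_bp_fraction: float
    total_bp: int


@dataclass
class TDBGIndex:
    k: int
    unitigs: list  # list[Unitig]
    tccs: list  # list[tuple[int, ...]] sorted transcript ordinals
    kmer_map: dict  # canonical k-mer -> (unitig_id, offset, "+"/"-")
    dlist_kmers: frozenset
    transcript_ids: tuple
    transcript_lengths: tuple

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def tcc_of_unitig(self, unitig_id: int) -> tuple:
        return self.tccs[self.unitigs[unitig_id].tcc_id]


def _oriented_succs(s: str, kmer_set) -> list:
    suf = s[1:]
    return [suf + b for b in "ACGT" if canonical(suf + b) in kmer_set]


def _oriented_preds(s: str, kmer_set) -> list:
    pre = s[:-1]
    return [b + pre for b in "ACGT" if canonical(b + pre) in kmer_set]


def build_index(transcripts: TranscriptSet, k: int = DEFAULT_K) -> TDBGIndex:
    """Build the compacted T-DBG with one TCC per unitig.

    k must be odd (no reverse-complement palindromes) and >= 15.  k-mers
    containing N are skipped.  Transcripts shorter than k contribute no
    k-mers but are retained in the transcript table.
    """
    if len(transcripts) == 0:
        raise ValueError("empty transcript set")
    if k < MIN_K or k % 2 == 0:
        raise ValueError(f"k must be an odd integer >= {MIN_K}, got {k}")

    # Canonical k-mer -> transcript compatibility label.
    kmer_tcc: dict = {}
    for ordinal, (_tid, seq) in enumerate(transcripts.records):
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            kmer_tcc.setdefault(canonical(km), set()).add(ordinal)
    if not kmer_tcc:
        raise ValueError(f"no transcript of length >= k={k}")
    label = {km: tuple(sorted(s)) for km, s in kmer_tcc.items()}

    # Compaction: extend maximal runs of identical-label k-mers along
    # unambiguous (single successor / single predecessor) links.  Canonical
    # k-mers are iterated in sorted order so the decomposition — including
    # the cut point of any pure cycle — is deterministic.
    visited = set()
    unitig_seqs = []  # (sequence, label)
    for start in sorted(label):
        if start in visited:
            continue
        visited.add(start)
        lab = label[start]

        fwd = []
        cur = start
        while True:
            nxt = _oriented_succs(cur, label)
            if len(nxt) != 1:
                break
            step = nxt[0]
            cstep = canonical(step)
            if cstep in visited or label[cstep] != lab:
                break
            if len(_oriented_preds(step, label)) != 1:
                break
            fwd.append(step)
            visited.add(cstep)
            cur = step

        bwd = []
        cur = start
        while True:
            prv = _oriented_preds(cur, label)
            if len(prv) != 1:
                break
            step = prv[0]
            cstep = canonical(step)
            if cstep in visited or label[cstep] != lab:
                break
            if len(_oriented_succs(step, label)) != 1:
                break
            bwd.append(step)
            visited.add(cstep)
            cur = step

        oriented = list(reversed(bwd)) + [start] + fwd
        seq = oriented[0] + "".join(s[-1] for s in oriented[1:])
        unitig_seqs.append((seq, lab))

    # Dedupe TCCs, fill k-mer map.
    tcc_index: dict = {}
    tccs: list = []
    kmer_map: dict = {}
    raw = []
    for uid, (seq, lab) in enumerate(unitig_seqs):
        tid_ = tcc_index.setdefault(lab, len(tccs))
        if tid_ == len(tccs):
            tccs.append(lab)
        for off in range(len(seq) - k + 1):
            km = seq[off : off + k]
            ckm = canonical(km)
            kmer_map[ckm] = (uid, off, "+" if km == ckm else "-")
        raw.append((seq, tid_))

    # Unitig adjacency at (k-1)-overlaps; all inter-unitig links occur at
    # unitig ends because internal k-mers have unique neighbors by
    # construction.
    preds_u = [set() for _ in raw]
    succs_u = [set() for _ in raw]
    for uid, (seq, _) in enumerate(raw):
        for t in _oriented_succs(seq[-k:], label):
            succs_u[uid].add(kmer_map[canonical(t)][0])
        for t in _oriented_preds(seq[:k], label):
            preds_u[uid].add(kmer_map[canonical(t)][0])

    unitigs = [
        Unitig(seq, tid_, frozenset(preds_u[uid]), frozenset(succs_u[uid]))
        for uid, (seq, tid_) in enumerate(raw)
    ]
    return TDBGIndex(
        k=k,
        unitigs=unitigs,
        tccs=tccs,
        kmer_map=kmer_map,
        dlist_kmers=frozenset(),
        transcript_ids=transcripts.ids,
        transcript_lengths=transcripts.lengths,
    )


def lookup_kmer(index: TDBGIndex, kmer: str) -> Optional[KmerHit]:
    """Canonical k-mer lookup; None on a miss.

    orientation is "forward" when the query itself is the stored canonical
    form and "reverse" when its reverse complement is.
    """
    if len(kmer) != index.k:
        raise ValueError(f"query length {len(kmer)} != k={index.k}")
    kmer = kmer.upper()
    ckm = canonical(kmer)
    ent = index.kmer_map.get(ckm)
    if ent is None:
        return None
    uid, off, _ = ent
    return KmerHit(
        unitig_id=uid,
        offset=off,
        orientation="forward" if kmer == ckm else "reverse",
        tcc=index.tccs[index.unitigs[uid].tcc_id],
    )


def build_dlist(
    index: TDBGIndex, dlist_sequences: Union[TranscriptSet, Iterable]
) -> TDBGIndex:
    """Attach distinguishing-list k-mers: canonical k-mers present in the
    supplied sequences but absent from the transcriptome."""
    if isinstance(dlist_sequences, TranscriptSet):
        seqs = [seq for _, seq in dlist_sequences.records]
    else:
        seqs = []
        for item in dlist_sequences:
            seq = item[1] if isinstance(item, (tuple, list)) else item
            _validate_sequence(seq, "dlist")
            seqs.append(seq)
    k = index.k
    novel = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            ckm = canonical(km)
            if ckm not in index.kmer_map:
                novel.add(ckm)
    return replace(index, dlist_kmers=frozenset(novel))


def _edge_set(index: TDBGIndex) -> set:
    edges = set()
    for uid, u in enumerate(index.unitigs):
        for v in u.predecessors | u.successors:
            edges.add(tuple(sorted((uid, v))))
    return edges


def graph_stats(index: TDBGIndex) -> GraphStats:
    """Node/edge counts and the bp share of the largest connected component.

    Nodes are unitigs; edges are undirected, deduplicated (k-1)-overlap
    links with self-loops counted once.
    """
    edges = _edge_set(index)
    g = nx.Graph()
    g.add_nodes_from(range(len(index.unitigs)))
    g.add_edges_from(edges)
    bp = [len(u.sequence) for u in index.unitigs]
    total = sum(bp)
    largest = max(
        (sum(bp[n] for n in comp) for comp in nx.connected_components(g)),
        default=0,
    )
    return GraphStats(
        k=index.k,
        n_nodes=len(index.unitigs),
        n_edges=len(edges),
        largest_component_bp_fraction=(largest / total) if total else 0.0,
        total_bp=total,
    )


def save_index(index: TDBGIndex, path) -> None:
    """Serialize to JSON.  The k-mer map is reconstructed from the unitig
    sequences on load, so the file stays compact and roundtrips exactly."""
    payload = {
        "format": "lrquant-tdbg",
        "format_version": INDEX_FORMAT_VERSION,
        "k": index.k,
        "transcript_ids": list(index.transcript_ids),
        "transcript_lengths": list(index.transcript_lengths),
        "tccs": [list(t) for t in index.tccs],
        "unitigs": [
            {
                "seq": u.sequence,
                "tcc_id": u.tcc_id,
                "preds": sorted(u.predecessors),
                "succs": sorted(u.successors),
            }
            for u in index.unitigs
        ],
        "dlist_kmers": sorted(index.dlist_kmers),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_index(path) -> TDBGIndex:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupt or truncated index file {path}: {e}") from e
    if payload.get("format") != "lrquant-tdbg":
        raise ValueError(f"{path} is not an lrquant index file")
    if payload.get("format_version") != INDEX_FORMAT_VERSION:
        raise ValueError(
            f"index format version {payload.get('format_version')} unsupported "
            f"(expected {INDEX_FORMAT_VERSION})"
        )
    k = payload["k"]
    unitigs = [
        Unitig(
            sequence=u["seq"],
            tcc_id=u["tcc_id"],
            predecessors=frozenset(u["preds"]),
            successors=frozenset(u["succs"]),
        )
        for u in payload["unitigs"]
    ]
    kmer_map: dict = {}
    for uid, u in enumerate(unitigs):
        seq = u.sequence
        for off in range(len(seq) - k + 1):
            km = seq[off : off + k]
            ckm = canonical(km)
            kmer_map[ckm] = (uid, off, "+" if km == ckm else "-")
    return TDBGIndex(
        k=k,
        unitigs=unitigs,
        tccs=[tuple(t) for t in payload["tccs"]],
        kmer_map=kmer_map,
        dlist_kmers=frozenset(payload["dlist_kmers"]),
        transcript_ids=tuple(payload["transcript_ids"]),
        transcript_lengths=tuple(payload["transcript_lengths"]),
    )
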