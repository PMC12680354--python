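"""Error-tolerant pseudoalignment of long reads against the T-DBG index.

Each read is assigned a transcript compatibility class (TCC) by a decision
cascade over the TCCs of its k-mers:

1. any examined k-mer on the d-list  -> the read is vetoed (``dlist_veto``);
2. no k-mer hits the index           -> ``unmapped``;
3. the intersection of all hit TCCs is non-empty -> that intersection
   (``intersection``) — the transcripts compatible with every mapped k-mer;
4. otherwise, if at least one hit k-mer maps uniquely to a single
   transcript, the most frequent TCC among those uniquely-mapping k-mers
   (``unique_mode``); ties go to the smallest transcript ordinal;
5. otherwise the most frequent TCC among all hit k-mers (``mode``); ties go
   to the class whose smallest ordinal is smallest, then lexicographically.

The intersection rule is kallisto's; the fallbacks make the method robust
to sequencing error, where a corrupted stretch can produce an isolated,
incompatible class that would otherwise empty the intersection.

K-mer examination uses contig skipping: once a k-mer lands in a unitig, only
the first, middle and end k-mers of the contig-consistent stretch are
checked.  If they agree the stretch is accepted at that cost; if they
disagree the stretch is scanned exhaustively.  Whenever the cascade falls
through to the mode branches the whole read is rescanned exhaustively, so
mode counts always equal those of a full k-mer-by-k-mer scan.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .tdbg import TDBGIndex, canonical

__all__ = [
    "ReadClassification",
    "TCCCounts",
    "classify_read",
    "pseudoalign_batch",
    "BRANCHES",
]

BRANCHES = ("intersection", "unique_mode", "mode", "unmapped", "dlist_veto")

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    tcc: Optional[tuple]  # sorted transcript ordinals, None if unmapped/vetoed
    branch: str
    n_kmers_examined: int
    read_length: int


@dataclass
class TCCCounts:
    counts: dict  # TCC tuple -> number of reads
    n_reads_total: int
    n_reads_mapped: int


def classify_read(index: TDBGIndex, read: str, read_id: str = "") -> ReadClassification:
    read = read.upper()
    bad = set(read) - _VALID
    if bad:
        raise ValueError(f"read {read_id!r}: invalid characters {sorted(bad)!r}")
    k = index.k
    L = len(read)
    if L < k:
        return ReadClassification(read_id, None, "unmapped", 0, L)

    kmer_map = index.kmer_map
    unitigs = index.unitigs
    tccs = index.tccs
    dlist = index.dlist_kmers
    npos = L - k + 1
    n_exam = 0

    DLIST = object()

    def probe(p):
        km = read[p : p + k]
        c = canonical(km)
        if c in dlist:
            return DLIST
        ent = kmer_map.get(c)
        if ent is None:
            return None
        uid, off, so = ent
        # read runs along the unitig's forward strand iff the query
        # orientation matches the stored orientation
        fwd = (km == c) == (so == "+")
        return (uid, off, fwd)

    hit_ids = []  # tcc_id per counted k-mer
    dlist_hit = False
    i = 0
    while i < npos:
        n_exam += 1
        h = probe(i)
        if h is DLIST:
            dlist_hit = True
            break
        if h is None:
            i += 1
            continue
        uid, off, fwd = h
        ulen = len(unitigs[uid].sequence) - k + 1
        remaining = (ulen - 1 - off) if fwd else off
        j = min(i + remaining, npos - 1)
        check = sorted({i, (i + j) // 2, j})
        ok = True
        for p in check[1:]:
            n_exam += 1
            h2 = probe(p)
            if h2 is DLIST:
                dlist_hit = True
                ok = False
                break
            exp_off = off + (p - i) if fwd else off - (p - i)
            if h2 is None or h2[0] != uid or h2[1] != exp_off or h2[2] != fwd:
                ok = False
                break
        if dlist_hit:
            break
        if ok:
            hit_ids.extend([unitigs[uid].tcc_id] * len(check))
        else:
            for p in range(i, j + 1):
                n_exam += 1
                h3 = probe(p)
                if h3 is DLIST:
                    dlist_hit = True
                    break
                if h3 is not None:
                    hit_ids.append(unitigs[h3[0]].tcc_id)
            if dlist_hit:
                break
        i = j + 1

    if dlist_hit:
        return ReadClassification(read_id, None, "dlist_veto", n_exam, L)
    if not hit_ids:
        return ReadClassification(read_id, None, "unmapped", n_exam, L)

    distinct = set(hit_ids)
    it = iter(distinct)
    inter = set(tccs[next(it)])
    for tcc_id in it:
        inter &= set(tccs[tcc_id])
        if not inter:
            break
    if inter:
        return ReadClassification(
            read_id, tuple(sorted(inter)), "intersection", n_exam, L
        )

    # Empty intersection: rescan exhaustively so mode counts match a full
    # scan regardless of what skipping examined.
    full = []
    for p in range(npos):
        n_exam += 1
        h = probe(p)
        if h is DLIST:
            return ReadClassification(read_id, None, "dlist_veto", n_exam, L)
        if h is not None:
            full.append(unitigs[h[0]].tcc_id)

    singles = [tcc_id for tcc_id in full if len(tccs[tcc_id]) == 1]
    pool = singles if singles else full
    cnt = Counter(pool)
    best = max(cnt.values())
    winner = min(tccs[tcc_id] for tcc_id, c in cnt.items() if c == best)
    branch = "unique_mode" if singles else "mode"
    return ReadClassification(read_id, winner, branch, n_exam, L)


def pseudoalign_batch(index: TDBGIndex, reads: Iterable):
    """Classify a stream of (read_id, sequence[, quality]) records.

    Returns (TCCCounts, classifications in input order, mapping_rate);
    mapping_rate is reported as 0.0 for an empty stream.
    """
    classifications = []
    counts: dict = {}
    n_total = 0
    n_mapped = 0
    for rec in reads:
        rid, seq = rec[0], rec[1]
        rc = classify_read(index, seq, rid)
        classifications.append(rc)
        n_total += 1
        if rc.tcc is not None:
            n_mapped += 1
            counts[rc.tcc] = counts.get(rc.tcc, 0) + 1
    rate = (n_mapped / n_total) if n_total else 0.0
    return TCCCounts(counts, n_total, n_mapped), classifications, rate
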