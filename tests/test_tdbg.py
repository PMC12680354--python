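"""Index construction, k-mer lookup, d-list, graph stats, serialization."""

import numpy as np
import pytest

from lrquant import (
    TranscriptSet,
    build_dlist,
    build_index,
    canonical,
    generate_transcriptome,
    graph_stats,
    load_index,
    lookup_kmer,
    reverse_complement,
    save_index,
)

from _oracles import naive_graph_stats, naive_kmer_tccs, naive_unitig_partition

RNG = np.random.default_rng(7)


def _random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def _partition_of(index):
    """Group canonical k-mers of an index by unitig, with the unitig's TCC."""
    blocks = {}
    for km, (uid, _, _) in index.kmer_map.items():
        blocks.setdefault(uid, set()).add(km)
    return {
        (frozenset(kms), index.tcc_of_unitig(uid)) for uid, kms in blocks.items()
    }


class TestBuildIndex:
    def test_single_transcript_no_branching(self):
        seq = _random_seq(np.random.default_rng(0), 100)
        ts = TranscriptSet.from_pairs([("t0", seq)])
        idx = build_index(ts, k=31)
        assert len(idx.unitigs) == 1
        assert len(idx.kmer_map) == 70
        assert idx.tccs == [(0,)]
        s = graph_stats(idx)
        assert (s.n_nodes, s.n_edges, s.largest_component_bp_fraction) == (1, 0, 1.0)

    @pytest.mark.parametrize(
        "k,err",
        [(30, "odd"), (13, "odd"), (0, "odd")],
    )
    def test_bad_k_rejected(self, k, err):
        ts = TranscriptSet.from_pairs([("t0", "ACGT" * 30)])
        with pytest.raises(ValueError):
            build_index(ts, k=k)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_index(TranscriptSet(()), k=31)
        with pytest.raises(ValueError):
            TranscriptSet.from_pairs([("t0", "ACGTX")])
        with pytest.raises(ValueError):
            TranscriptSet.from_pairs([("t0", "ACGT"), ("t0", "ACGT")])

    def test_short_transcript_kept_without_kmers(self):
        long = _random_seq(np.random.default_rng(1), 80)
        ts = TranscriptSet.from_pairs([("short", "ACGTACGT"), ("long", long)])
        idx = build_index(ts, k=31)
        assert idx.transcript_lengths == (8, 80)
        assert all(0 not in tcc for tcc in idx.tccs)

    def test_n_kmers_skipped(self):
        rng = np.random.default_rng(2)
        seq = _random_seq(rng, 50) + "N" + _random_seq(rng, 50)
        ts = TranscriptSet.from_pairs([("t0", seq)])
        idx = build_index(ts, k=31)
        # only the two clean 50 bp halves contribute: 2 * (50 - 31 + 1)
        assert len(idx.kmer_map) == 40

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("k", [15, 21])
    def test_compaction_matches_bruteforce(self, seed, k):
        """Unitig decomposition, TCCs, and graph stats equal the naive
        k-mer-graph compaction oracle on random shared-block fixtures."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 12))
        blocks = [
            (int(a), int(b), int(rng.integers(k + 2, 60)))
            for a, b in [rng.choice(n, 2, replace=False) for _ in range(2)]
        ]
        ts = generate_transcriptome(
            n, length_range=(60, 200), shared_blocks=blocks, seed=seed
        )
        idx = build_index(ts, k=k)
        labels = {
            km: tuple(sorted(s)) for km, s in naive_kmer_tccs(ts.records, k).items()
        }
        assert _partition_of(idx) == naive_unitig_partition(labels)
        s = graph_stats(idx)
        n_nodes, n_edges, frac = naive_graph_stats(labels, k)
        assert (s.n_nodes, s.n_edges) == (n_nodes, n_edges)
        assert s.largest_component_bp_fraction == pytest.approx(frac)

    def test_two_shared_transcripts_against_oracle(self):
        """The spec'd shared-internal-block case at small k."""
        rng = np.random.default_rng(5)
        a, b = _random_seq(rng, 40), _random_seq(rng, 40)
        shared = _random_seq(rng, 20)
        t1 = a[:10] + shared + a[30:]
        t2 = b[:10] + shared + b[30:]
        ts = TranscriptSet.from_pairs([("t1", t1), ("t2", t2)])
        idx = build_index(ts, k=15)
        labels = {
            km: tuple(sorted(s)) for km, s in naive_kmer_tccs(ts.records, 15).items()
        }
        assert _partition_of(idx) == naive_unitig_partition(labels)

    def test_kmer_completeness_and_tcc_soundness(self, toy_transcripts, toy_index):
        naive = naive_kmer_tccs(toy_transcripts.records, toy_index.k)
        k = toy_index.k
        for ordinal, (_tid, seq) in enumerate(toy_transcripts.records):
            for i in range(len(seq) - k + 1):
                hit = lookup_kmer(toy_index, seq[i : i + k])
                assert hit is not None
                assert ordinal in hit.tcc
        # each unitig's TCC is exactly the transcripts containing all its k-mers
        for uid in range(len(toy_index.unitigs)):
            kms = [
                km for km, (u, _, _) in toy_index.kmer_map.items() if u == uid
            ]
            expected = frozenset.intersection(*(naive[km] for km in kms))
            assert frozenset(toy_index.tcc_of_unitig(uid)) == expected

    def test_larger_k_no_more_complex(self):
        """Repeats shorter than the larger k vanish at that k, so node and
        edge counts are monotone non-increasing in k."""
        for seed in range(5):
            ts = generate_transcriptome(
                8,
                length_range=(200, 400),
                shared_blocks=[(0, 1, 45), (2, 3, 62), (4, 5, 50)],
                seed=seed,
            )
            lo = graph_stats(build_index(ts, k=31))
            hi = graph_stats(build_index(ts, k=63))
            assert hi.n_nodes <= lo.n_nodes
            assert hi.n_edges <= lo.n_edges


class TestLookup:
    def test_forward_reverse_and_miss(self, toy_transcripts, toy_index):
        k = toy_index.k
        km = toy_transcripts.records[0][1][:k]
        fwd = lookup_kmer(toy_index, km)
        rev = lookup_kmer(toy_index, reverse_complement(km))
        assert fwd is not None and 0 in fwd.tcc
        assert (rev.unitig_id, rev.offset, rev.tcc) == (
            fwd.unitig_id,
            fwd.offset,
            fwd.tcc,
        )
        assert {fwd.orientation, rev.orientation} == {"forward", "reverse"}
        # absent k-mer: mutate until it misses
        absent = "A" * k
        assert lookup_kmer(toy_index, absent) is None or canonical(absent) in toy_index.kmer_map
        with pytest.raises(ValueError):
            lookup_kmer(toy_index, "ACGT")


class TestDlist:
    def test_identical_sequences_yield_empty(self, toy_transcripts, toy_index):
        idx = build_dlist(toy_index, toy_transcripts)
        assert idx.dlist_kmers == frozenset()

    def test_novel_sequence_sliding_window_count(self, toy_index):
        k = toy_index.k
        rng = np.random.default_rng(9)
        while True:
            novel = _random_seq(rng, 2 * k)
            kms = {canonical(novel[i : i + k]) for i in range(k + 1)}
            if len(kms) == k + 1 and not (kms & set(toy_index.kmer_map)):
                break
        idx = build_dlist(toy_index, [novel])
        assert len(idx.dlist_kmers) == k + 1

    def test_boundary_overlap_equals_set_difference(self, toy_transcripts, toy_index):
        """A d-list sequence straddling transcript sequence and novel
        sequence flags exactly the novel k-mers."""
        k = toy_index.k
        rng = np.random.default_rng(10)
        dseq = toy_transcripts.records[0][1][:60] + _random_seq(rng, 60)
        idx = build_dlist(toy_index, [dseq])
        expected = {
            canonical(dseq[i : i + k]) for i in range(len(dseq) - k + 1)
        } - set(toy_index.kmer_map)
        assert idx.dlist_kmers == expected


class TestGraphStats:
    def test_two_disjoint_transcripts_split_bp_evenly(self):
        rng = np.random.default_rng(12)
        ts = TranscriptSet.from_pairs(
            [("t0", _random_seq(rng, 200)), ("t1", _random_seq(rng, 200))]
        )
        idx = build_index(ts, k=31)
        s = graph_stats(idx)
        if s.n_nodes == 2:  # no chance k-mer sharing
            assert s.largest_component_bp_fraction == pytest.approx(0.5)
        assert s.total_bp == sum(len(u.sequence) for u in idx.unitigs)


class TestSerialization:
    def test_roundtrip(self, tmp_path, toy_transcripts, toy_index):
        idx = build_dlist(toy_index, [toy_transcripts.records[0][1][:40] + "ACGTTGCA" * 10])
        path = tmp_path / "index.lrk"
        save_index(idx, path)
        loaded = load_index(path)
        assert loaded == idx
        assert graph_stats(loaded) == graph_stats(idx)

    def test_corrupt_files_rejected(self, tmp_path):
        empty = tmp_path / "empty.lrk"
        empty.write_text("")
        with pytest.raises(ValueError):
            load_index(empty)
        bad = tmp_path / "bad.lrk"
        bad.write_text('{"format": "lrquant-tdbg", "format_version": 99}')
        with pytest.raises(ValueError):
            load_index(bad)
        trunc = tmp_path / "trunc.lrk"
        trunc.write_text('{"format": "lrquant-tdbg", "format_ver')
        with pytest.raises(ValueError):
            load_index(trunc)
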