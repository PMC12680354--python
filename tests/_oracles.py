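"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's index/classify code paths: they
enumerate every k-mer naively, use their own reverse-complement and
compaction logic, and apply the decision rules directly to k-mer TCC sets.
"""

from collections import Counter

import networkx as nx

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def canon(kmer):
    r = rc(kmer)
    return kmer if kmer <= r else r


def naive_kmer_tccs(records, k):
    """canonical k-mer -> frozenset of transcript ordinals (N k-mers skipped)."""
    out = {}
    for ordinal, (_tid, seq) in enumerate(records):
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            out.setdefault(canon(km), set()).add(ordinal)
    return {km: frozenset(s) for km, s in out.items()}


def _succs(s, kmer_set):
    return [s[1:] + b for b in "ACGT" if canon(s[1:] + b) in kmer_set]


def _preds(s, kmer_set):
    return [b + s[:-1] for b in "ACGT" if canon(b + s[:-1]) in kmer_set]


def _merge_graph(labels):
    """Undirected graph over canonical k-mers with an edge per mergeable
    (unique-successor/unique-predecessor, identical-label) adjacency."""
    g = nx.Graph()
    g.add_nodes_from(labels)
    for c in labels:
        for s in (c, rc(c)):
            nxt = _succs(s, labels)
            if len(nxt) == 1:
                t = nxt[0]
                ct = canon(t)
                if labels[ct] == labels[c] and len(_preds(t, labels)) == 1:
                    g.add_edge(c, ct)
    return g


def naive_unitig_partition(labels):
    """Partition of canonical k-mers into unitig blocks: set of
    (frozenset of k-mers, label) pairs."""
    g = _merge_graph(labels)
    return {
        (frozenset(comp), labels[next(iter(comp))])
        for comp in nx.connected_components(g)
    }


def naive_graph_stats(labels, k):
    """(n_nodes, n_edges, largest_component_bp_fraction) from first principles.

    Blocks come from the merge graph; inter-block edges from non-mergeable
    adjacencies, plus a self-loop for any cyclic block (every adjacency
    internal).  Block bp = #kmers + k - 1.
    """
    g = _merge_graph(labels)
    comps = list(nx.connected_components(g))
    block_of = {}
    for bi, comp in enumerate(comps):
        for node in comp:
            block_of[node] = bi
    merge_edges = {frozenset((u, v)) for u, v in g.edges}
    edges = set()
    for c in labels:
        for s in (c, rc(c)):
            for t in _succs(s, labels):
                ct = canon(t)
                if frozenset((c, ct)) not in merge_edges:
                    edges.add(tuple(sorted((block_of[c], block_of[ct]))))
    for bi, comp in enumerate(comps):
        n_internal = sum(
            1 for u, v in g.edges if u in comp
        )
        if n_internal == len(comp) and len(comp) > 0:  # cycle: closes on itself
            edges.add((bi, bi))
    bp = [len(comp) + k - 1 for comp in comps]
    cg = nx.Graph()
    cg.add_nodes_from(range(len(comps)))
    cg.add_edges_from(edges)
    total = sum(bp)
    largest = max(sum(bp[n] for n in cc) for cc in nx.connected_components(cg))
    return len(comps), len(edges), largest / total


def exhaustive_classify(kmer_tccs, read, k, dlist=frozenset()):
    """Apply the decision cascade to the full k-mer multiset of a read.

    Returns (branch, tcc tuple or None).
    """
    if len(read) < k:
        return "unmapped", None
    hits = []
    for i in range(len(read) - k + 1):
        c = canon(read[i : i + k])
        if c in dlist:
            return "dlist_veto", None
        if c in kmer_tccs:
            hits.append(kmer_tccs[c])
    if not hits:
        return "unmapped", None
    inter = frozenset.intersection(*hits)
    if inter:
        return "intersection", tuple(sorted(inter))
    singles = [h for h in hits if len(h) == 1]
    pool = singles if singles else hits
    cnt = Counter(tuple(sorted(h)) for h in pool)
    best = max(cnt.values())
    winner = min(t for t, n in cnt.items() if n == best)
    return ("unique_mode" if singles else "mode"), winner
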