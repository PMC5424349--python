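"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: a triple-loop
Needleman–Wunsch DP for optimal global alignment scores, a
descendant-enumeration subtree summer, and a literal per-row filter
predicate.
"""

from __future__ import annotations


def nw_score_oracle(a: str, b: str, match=1.0, mismatch=-2.0, gap=-2.5) -> float:
    """Optimal global alignment score by the plain O(nm) recurrence."""
    n, m = len(a), len(b)
    prev = [gap * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [gap * i] + [0.0] * m
        for j in range(1, m + 1):
            ai, bj = a[i - 1], b[j - 1]
            s = match if (ai == bj and ai != "N" and bj != "N") else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def subtree_sum_oracle(tree, leaf_values, rank):
    """Per-node descendant-leaf sums at ``rank`` by explicit enumeration."""

    def descendant_leaves(taxid):
        stack, found = [taxid], []
        while stack:
            t = stack.pop()
            kids = tree.children(t)
            if t in leaf_values:
                found.append(t)
            stack.extend(kids)
        return found

    out = {}
    nodes_at_rank = [t for t in iter_nodes(tree) if tree.rank(t) == rank]
    for node in nodes_at_rank:
        total = sum(leaf_values[t] for t in descendant_leaves(node))
        if any(t in leaf_values for t in descendant_leaves(node)):
            out[node] = total
    return out


def iter_nodes(tree):
    stack = [tree.root]
    while stack:
        t = stack.pop()
        yield t
        stack.extend(tree.children(t))


def filter_predicate_oracle(hits, min_identity, min_coverage, top_percent):
    """Literal evaluation of the retention predicate, row by row (no
    per-subject dedup)."""
    best = max(h.bitscore for h in hits)
    floor = best * (1 - top_percent / 100.0)
    return [
        h
        for h in hits
        if h.pct_identity >= min_identity
        and 100.0 * (h.qend - h.qstart + 1) / h.qlen >= min_coverage
        and h.bitscore >= floor
    ]
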