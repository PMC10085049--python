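"""Independent brute-force oracles for the interval engine.

These deliberately avoid the sorted-sweep implementation: merging is done
as explicit connected components of the pairwise overlap graph (networkx),
and matching by exhaustive all-pairs reciprocal overlap computed with
plain arithmetic.
"""

from __future__ import annotations

import networkx as nx


def overlap_len(a: tuple, b: tuple) -> int:
    """Inclusive overlap of (chrom, start, end) tuples; 0 across chroms."""
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]) + 1)


def brute_force_merge(intervals: list[tuple], min_overlap_bp: int = 1) -> list[tuple]:
    """Merged spans via explicit overlap graph + connected components.

    ``intervals`` are (chrom, start, end) tuples; returns sorted
    (chrom, min_start, max_end) spans, one per component.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(intervals)))
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            if overlap_len(intervals[i], intervals[j]) >= min_overlap_bp:
                g.add_edge(i, j)
    spans = []
    for comp in nx.connected_components(g):
        members = [intervals[i] for i in comp]
        spans.append(
            (
                members[0][0],
                min(m[1] for m in members),
                max(m[2] for m in members),
            )
        )
    return sorted(spans)


def brute_force_reciprocal_pairs(
    set_a: list[tuple], set_b: list[tuple], min_ro: float = 0.5
) -> set[tuple]:
    """All (index_a, index_b) pairs with RO >= min_ro, by exhaustive search."""
    pairs = set()
    for i, a in enumerate(set_a):
        len_a = a[2] - a[1] + 1
        for j, b in enumerate(set_b):
            ov = overlap_len(a, b)
            if ov == 0:
                continue
            len_b = b[2] - b[1] + 1
            if min(ov / len_a, ov / len_b) >= min_ro:
                pairs.add((i, j))
    return pairs
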