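"""Genomic interval algebra on 1-based inclusive coordinates.

The three primitives here are the computational core of consensus CNVR
construction:

* :func:`merge_calls` — transitive merging of intervals that overlap by at
  least ``min_overlap_bp`` (connected components of the overlap graph),
* :func:`reciprocal_overlap` / :func:`reciprocal_match` — the 50% reciprocal
  overlap criterion used to declare two regions "the same" across callers,
  platforms or studies,
* :func:`region_frequency` — carrier frequency against an explicit cohort
  size.

Implementation is a single sorted sweep per chromosome: with intervals
sorted by start, an interval belongs to the current component iff it
overlaps the member with the largest end seen so far by at least
``min_overlap_bp``, so the sweep computes exact connected components in
O(n log n).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .model import (
    CNVR,
    CNVRSet,
    CNVRType,
    CNVType,
    chrom_sort_key,
)


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap length in bp between two 1-based inclusive intervals (>= 0)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def reciprocal_overlap(a, b) -> float:
    """Reciprocal overlap between two interval-like objects.

    Returns ``min(ov / len(a), ov / len(b))`` where ``ov`` is the inclusive
    overlap length; 0.0 for different chromosomes or disjoint intervals.
    """
    if a.chrom != b.chrom:
        return 0.0
    ov = overlap_bp(a.start, a.end, b.start, b.end)
    if ov == 0:
        return 0.0
    len_a = a.end - a.start + 1
    len_b = b.end - b.start + 1
    return min(ov / len_a, ov / len_b)


def _member_cnv_types(member) -> set[CNVType]:
    """CNV types contributed by a member call or region."""
    t = getattr(member, "cnv_type", None)
    if t is not None:
        return {CNVType(t)}
    rt = getattr(member, "cnvr_type", None)
    if rt == CNVRType.DELETION:
        return {CNVType.DEL}
    if rt == CNVRType.DUPLICATION:
        return {CNVType.DUP}
    if rt == CNVRType.COMPLEX:
        return {CNVType.DEL, CNVType.DUP}
    raise TypeError(f"member {member!r} has neither cnv_type nor cnvr_type")


def derive_region_type(members: Iterable) -> CNVRType:
    """DELETION iff all members DEL, DUPLICATION iff all DUP, else COMPLEX."""
    types: set[CNVType] = set()
    for m in members:
        types |= _member_cnv_types(m)
    if types == {CNVType.DEL}:
        return CNVRType.DELETION
    if types == {CNVType.DUP}:
        return CNVRType.DUPLICATION
    return CNVRType.COMPLEX


def _member_carriers(member) -> frozenset[str]:
    sid = getattr(member, "sample_id", None)
    if sid is not None:
        return frozenset([sid])
    return frozenset(getattr(member, "carriers", frozenset()))


def _member_provenance(member) -> frozenset[str]:
    src = getattr(member, "source", None)
    if src is not None:
        return frozenset([src.value if hasattr(src, "value") else str(src)])
    return frozenset(getattr(member, "provenance", frozenset()))


def _flatten_members(member) -> list:
    """Underlying CNV calls of a member (itself, or a region's members)."""
    inner = getattr(member, "members", None)
    if inner:
        return list(inner)
    return [member]


def build_region(members: Sequence, region_id: str) -> CNVR:
    """Assemble a CNVR from member calls/regions: span, type, carriers."""
    if not members:
        raise ValueError("cannot build a region from zero members")
    chroms = {m.chrom for m in members}
    if len(chroms) != 1:
        raise ValueError(f"members span multiple chromosomes: {chroms}")
    carriers: frozenset[str] = frozenset()
    provenance: frozenset[str] = frozenset()
    flat: list = []
    for m in members:
        carriers |= _member_carriers(m)
        provenance |= _member_provenance(m)
        flat.extend(_flatten_members(m))
    return CNVR(
        region_id=region_id,
        chrom=next(iter(chroms)),
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        cnvr_type=derive_region_type(members),
        members=flat,
        carriers=carriers,
        provenance=provenance,
    )


def merge_calls(
    items: Sequence,
    min_overlap_bp: int = 1,
    id_prefix: str = "CNVR",
) -> list[CNVR]:
    """Transitively merge interval-like items overlapping by >= min_overlap_bp.

    Items may be CNV calls or CNVRs (mixing is allowed). Output regions are
    the connected components of the pairwise-overlap graph, each spanning
    min(start)-max(end) of its component, typed by the member-type rule,
    sorted by (chrom, start) with sequential ids.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    ordered = sorted(
        items, key=lambda x: (chrom_sort_key(x.chrom), x.start, x.end)
    )
    coarse = _sweep_components(ordered)
    if min_overlap_bp == 1:
        components = coarse
    else:
        # >= 1 bp components are a superset partition of >= k bp components;
        # refine each by exact pairwise union-find (a short interval nested
        # under a component's span may still overlap no member by >= k).
        components = []
        for cluster in coarse:
            components.extend(_refine_components(cluster, min_overlap_bp))
        components.sort(key=lambda c: (chrom_sort_key(c[0].chrom), c[0].start))
    return [
        build_region(comp, f"{id_prefix}{i + 1}")
        for i, comp in enumerate(components)
    ]


def _sweep_components(ordered: Sequence) -> list[list]:
    """Connected components under >= 1 bp overlap by a single sorted sweep.

    With starts sorted, an interval overlaps the component's farthest-
    reaching member (whose start is not greater) iff start <= max_end.
    """
    components: list[list] = []
    current: list = []
    cur_chrom: Optional[str] = None
    cur_max_end = -1
    for it in ordered:
        if current and it.chrom == cur_chrom and it.start <= cur_max_end:
            current.append(it)
            cur_max_end = max(cur_max_end, it.end)
        else:
            if current:
                components.append(current)
            current = [it]
            cur_chrom = it.chrom
            cur_max_end = it.end
    if current:
        components.append(current)
    return components


def _refine_components(cluster: Sequence, k: int) -> list[list]:
    """Exact >= k bp connected components within one >= 1 bp cluster."""
    n = len(cluster)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = cluster[i], cluster[j]
            if overlap_bp(a.start, a.end, b.start, b.end) >= k:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(cluster[i])
    return sorted(groups.values(), key=lambda c: (c[0].start, c[0].end))


def reciprocal_match(
    set_a: CNVRSet | Sequence[CNVR],
    set_b: CNVRSet | Sequence[CNVR],
    min_ro: float = 0.5,
) -> list[tuple[CNVR, CNVR]]:
    """All (regionA, regionB) pairs with reciprocal overlap >= min_ro.

    Many-to-many pairs are allowed; deduplication into a final region set is
    the caller's responsibility. Pairs are sorted by (chrom, startA).
    """
    if not (0 < min_ro <= 1):
        raise ValueError("min_ro must be in (0, 1]")
    regions_a = list(set_a.regions if isinstance(set_a, CNVRSet) else set_a)
    regions_b = list(set_b.regions if isinstance(set_b, CNVRSet) else set_b)
    by_chrom_b: dict[str, list[CNVR]] = {}
    for r in regions_b:
        by_chrom_b.setdefault(r.chrom, []).append(r)
    for lst in by_chrom_b.values():
        lst.sort(key=lambda r: (r.start, r.end))
    pairs: list[tuple[CNVR, CNVR]] = []
    for ra in sorted(
        regions_a, key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end)
    ):
        for rb in by_chrom_b.get(ra.chrom, ()):
            if rb.start > ra.end:
                break
            if reciprocal_overlap(ra, rb) >= min_ro:
                pairs.append((ra, rb))
    return pairs


def region_frequency(region: CNVR, n_individuals: int) -> float:
    """Carrier frequency of a region in a cohort of ``n_individuals``.

    The denominator is always explicit: which cohort a frequency refers to
    (e.g. genotyped vs sequenced animals) is an analysis decision.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if len(region.carriers) > n_individuals:
        raise ValueError(
            f"region {region.region_id} has more carriers "
            f"({len(region.carriers)}) than individuals ({n_individuals})"
        )
    return len(region.carriers) / n_individuals


def any_overlap(region: CNVR, others: Sequence[CNVR], min_bp: int = 1) -> bool:
    """True if ``region`` overlaps any of ``others`` by >= min_bp."""
    for o in others:
        if o.chrom != region.chrom:
            continue
        if overlap_bp(region.start, region.end, o.start, o.end) >= min_bp:
            return True
    return False


def covered_bp(items: Sequence) -> int:
    """Total bp covered by the union of interval-like items."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for it in items:
        by_chrom.setdefault(it.chrom, []).append((it.start, it.end))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    return total
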