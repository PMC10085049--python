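"""Construction of the high-confidence CNVR sets.

Two consensus schemes are implemented:

* **population-level (POP)** — per-caller calls are merged into regions
  (>= 1 bp transitive overlap); read-depth and paired-end regions from
  sequencing are reconciled at 50% reciprocal overlap into a sequencing
  consensus set (SEQ); SEQ is then reconciled with the SNP-array region set
  (GEN) at the same criterion, and only regions carried by at least 5% of
  the cohort are kept;
* **per-animal (ANI)** — for each individual with both sequencing and array
  data, calls from the two platforms that reciprocally overlap >= 50% are
  retained and pooled across individuals, then merged into regions.

The union of the two sets (>= 1 bp merge) is the final unique set. The
region reported for a cross-set match is the span union of the matched
regions, so every supporting call is contained; many-to-many matches are
resolved by transitive clustering of match edges. A consensus region's type
is re-derived from all member calls, so mixed deletion/duplication support
yields COMPLEX.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .intervals import (
    any_overlap,
    build_region,
    covered_bp,
    merge_calls,
    reciprocal_match,
    reciprocal_overlap,
    region_frequency,
)
from .model import CNVR, CNVRSet, CNVCall, SetKind, sort_regions

logger = logging.getLogger(__name__)


@dataclass
class SetSummary:
    """Size statistics for one CNVR set."""

    n_regions: int
    n_deletion: int
    n_duplication: int
    n_complex: int
    mean_size: float
    min_size: int
    max_size: int
    median_size: float
    sd_size: float
    total_covered_bp: int

    @classmethod
    def from_set(cls, cnvr_set: CNVRSet) -> "SetSummary":
        sizes = [r.length for r in cnvr_set.regions]
        types = [r.cnvr_type.value for r in cnvr_set.regions]
        if not sizes:
            return cls(0, 0, 0, 0, 0.0, 0, 0, 0.0, 0.0, 0)
        return cls(
            n_regions=len(sizes),
            n_deletion=types.count("DELETION"),
            n_duplication=types.count("DUPLICATION"),
            n_complex=types.count("COMPLEX"),
            mean_size=statistics.fmean(sizes),
            min_size=min(sizes),
            max_size=max(sizes),
            median_size=statistics.median(sizes),
            sd_size=statistics.stdev(sizes) if len(sizes) > 1 else 0.0,
            total_covered_bp=covered_bp(cnvr_set.regions),
        )


@dataclass
class BuildReport:
    """Per-stage bookkeeping for one pipeline run."""

    input_calls: dict[str, int] = field(default_factory=dict)
    retained_calls: dict[str, int] = field(default_factory=dict)
    set_summaries: dict[str, SetSummary] = field(default_factory=dict)
    shared_pop_ani: int = 0

    def record_set(self, name: str, cnvr_set: CNVRSet) -> None:
        self.set_summaries[name] = SetSummary.from_set(cnvr_set)

    def to_dict(self) -> dict:
        return {
            "input_calls": self.input_calls,
            "retained_calls": self.retained_calls,
            "set_summaries": {
                k: vars(v) for k, v in self.set_summaries.items()
            },
            "shared_pop_ani": self.shared_pop_ani,
        }


def _cluster_match_pairs(
    pairs: Sequence[tuple[CNVR, CNVR]]
) -> list[list[CNVR]]:
    """Connected components over match edges (transitive clustering)."""
    parent: dict[int, int] = {}
    obj: dict[int, CNVR] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a, b in pairs:
        for r in (a, b):
            if id(r) not in parent:
                parent[id(r)] = id(r)
                obj[id(r)] = r
    for a, b in pairs:
        union(id(a), id(b))
    clusters: dict[int, list[CNVR]] = {}
    for key, region in obj.items():
        clusters.setdefault(find(key), []).append(region)
    out = [sorted(c, key=lambda r: (r.start, r.end)) for c in clusters.values()]
    return sorted(out, key=lambda c: (c[0].chrom, c[0].start))


def _regions_from_clusters(
    clusters: Sequence[Sequence[CNVR]], id_prefix: str
) -> list[CNVR]:
    regions = [
        build_region(list(cluster), f"{id_prefix}_tmp{i}")
        for i, cluster in enumerate(clusters)
    ]
    regions = sort_regions(regions)
    for i, r in enumerate(regions, start=1):
        r.region_id = f"{id_prefix}{i}"
    return regions


def build_cnvr_seq(
    cnvnator_calls: Sequence[CNVCall],
    delly_calls: Sequence[CNVCall],
    min_ro: float = 0.5,
) -> CNVRSet:
    """Sequencing consensus regions: read-depth vs paired-end agreement.

    Each caller's (already filtered) calls are merged into per-caller
    regions at >= 1 bp; regions participating in a >= ``min_ro`` reciprocal
    match across the two callers are transitively clustered and each
    cluster's span union becomes a SEQ region.
    """
    if not cnvnator_calls or not delly_calls:
        logger.warning(
            "build_cnvr_seq: empty input (%d CNVnator, %d DELLY calls); "
            "returning empty SEQ set",
            len(cnvnator_calls), len(delly_calls),
        )
        return CNVRSet(name="CNVR_SEQ", kind=SetKind.SEQ, regions=[])
    regions_rd = merge_calls(cnvnator_calls, id_prefix="RD")
    regions_pe = merge_calls(delly_calls, id_prefix="PE")
    pairs = reciprocal_match(regions_rd, regions_pe, min_ro=min_ro)
    clusters = _cluster_match_pairs(pairs)
    return CNVRSet(
        name="CNVR_SEQ",
        kind=SetKind.SEQ,
        regions=_regions_from_clusters(clusters, "SEQ"),
    )


def build_cnvr_gen(penncnv_calls: Sequence[CNVCall]) -> CNVRSet:
    """SNP-array regions: >= 1 bp transitive merge of filtered array calls."""
    return CNVRSet(
        name="CNVR_GEN",
        kind=SetKind.GEN,
        regions=merge_calls(penncnv_calls, id_prefix="GEN"),
    )


def build_cnvr_pop(
    gen: CNVRSet,
    seq: CNVRSet,
    n_individuals: int,
    min_freq: float = 0.05,
    min_ro: float = 0.5,
) -> CNVRSet:
    """Population-level consensus: GEN x SEQ matches carried by >= min_freq.

    Matched clusters become span-union regions with carriers pooled across
    all member calls; a region is kept iff its carrier frequency over the
    explicit ``n_individuals`` cohort is at least ``min_freq``.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    pairs = reciprocal_match(gen, seq, min_ro=min_ro)
    clusters = _cluster_match_pairs(pairs)
    regions = _regions_from_clusters(clusters, "POP")
    kept = []
    for r in regions:
        r.frequency = region_frequency(r, n_individuals)
        if r.frequency >= min_freq:
            kept.append(r)
    for i, r in enumerate(kept, start=1):
        r.region_id = f"POP{i}"
    return CNVRSet(name="CNVR_POP", kind=SetKind.POP, regions=kept)


def build_cnvr_ani(
    penncnv_by_sample: Mapping[str, Sequence[CNVCall]],
    cnvnator_by_sample: Mapping[str, Sequence[CNVCall]],
    samples: Sequence[str],
    min_ro: float = 0.5,
) -> CNVRSet:
    """Per-animal dual-platform consensus regions.

    For each individual with both array and sequencing calls, call pairs
    (array x read-depth) with reciprocal overlap >= ``min_ro`` are retained
    — type-agnostic, with the region type re-derived later — pooled across
    individuals, and merged at >= 1 bp. Only the array caller and the
    read-depth caller participate, as both are per-sample dosage signals.
    """
    retained: list[CNVCall] = []
    for sample in samples:
        if sample not in penncnv_by_sample or sample not in cnvnator_by_sample:
            logger.warning(
                "build_cnvr_ani: sample %s lacks calls on one platform; excluded",
                sample,
            )
            continue
        arr = penncnv_by_sample[sample]
        rd = cnvnator_by_sample[sample]
        kept: set[CNVCall] = set()
        for a in arr:
            for b in rd:
                if reciprocal_overlap(a, b) >= min_ro:
                    kept.add(a)
                    kept.add(b)
        retained.extend(
            sorted(kept, key=lambda c: (c.chrom, c.start, c.end, c.source.value))
        )
    return CNVRSet(
        name="CNVR_ANI",
        kind=SetKind.ANI,
        regions=merge_calls(retained, id_prefix="ANI"),
    )


def build_unique_set(pop: CNVRSet, ani: CNVRSet) -> tuple[CNVRSet, int]:
    """Merge POP and ANI into the final unique set; count shared POP regions.

    Returns ``(unique_set, shared_count)`` where ``shared_count`` is the
    number of POP regions overlapping (>= 1 bp) at least one ANI region.
    Each unique region's provenance records the contributing set(s)
    (POP, ANI or both).
    """
    tagged: list[CNVR] = []
    for r in pop.regions:
        t = CNVR(**{**vars(r)})
        t.provenance = r.provenance | {"POP"}
        tagged.append(t)
    for r in ani.regions:
        t = CNVR(**{**vars(r)})
        t.provenance = r.provenance | {"ANI"}
        tagged.append(t)
    unique_regions = merge_calls(tagged, id_prefix="CNVR") if tagged else []
    shared = sum(
        1 for r in pop.regions if any_overlap(r, ani.regions, min_bp=1)
    )
    return (
        CNVRSet(name="CNVR_UNIQUE", kind=SetKind.UNIQUE, regions=unique_regions),
        shared,
    )
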