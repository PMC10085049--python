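"""Comparison of a CNVR set against external catalogues of published CNVRs.

External calls from multiple studies are first merged (>= 1 bp) into one
catalogue region set with study provenance; a query region and a catalogue
region are then "considered equal" when their reciprocal overlap is at
least 50%. Coordinates must already be on the query set's assembly —
cross-assembly liftover is the user's responsibility and mixed-assembly
input is refused when assembly labels are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .intervals import merge_calls, reciprocal_overlap
from .model import CNVR, CNVRSet, CNVRType, ExternalCNVR, SetKind, chrom_sort_key

_TYPE_MAP = {
    "DEL": CNVRType.DELETION,
    "DELETION": CNVRType.DELETION,
    "LOSS": CNVRType.DELETION,
    "DUP": CNVRType.DUPLICATION,
    "DUPLICATION": CNVRType.DUPLICATION,
    "GAIN": CNVRType.DUPLICATION,
    "COMPLEX": CNVRType.COMPLEX,
}


@dataclass(frozen=True)
class _ExternalAsCall:
    """Adapter presenting an external record to the interval engine."""

    chrom: str
    start: int
    end: int
    cnvr_type: CNVRType
    study_id: str

    @property
    def provenance(self) -> frozenset[str]:
        return frozenset([self.study_id])

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset()


def build_external_set(
    raw_calls: Sequence[ExternalCNVR],
    assembly: Optional[str] = None,
    query_assembly: Optional[str] = None,
) -> CNVRSet:
    """Merge external records (>= 1 bp, across studies) into one catalogue.

    Records with unknown type strings are treated as COMPLEX for the
    purpose of merged-region typing (unknown dosage direction).
    """
    if assembly and query_assembly and assembly != query_assembly:
        raise ValueError(
            f"catalogue assembly {assembly!r} != query assembly "
            f"{query_assembly!r}; liftover required before comparison"
        )
    adapted = [
        _ExternalAsCall(
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            cnvr_type=_TYPE_MAP.get(r.cnv_type.upper(), CNVRType.COMPLEX),
            study_id=r.study_id,
        )
        for r in raw_calls
    ]
    return CNVRSet(
        name="EXTERNAL",
        kind=SetKind.EXTERNAL,
        regions=merge_calls(adapted, id_prefix="EXT") if adapted else [],
    )


@dataclass
class ExternalMatchReport:
    """Outcome of comparing a query set against an external catalogue."""

    matches: dict[str, list[str]] = field(default_factory=dict)
    studies_per_region: dict[str, list[str]] = field(default_factory=dict)
    matched_count: int = 0
    unmatched_fraction: float = 1.0

    def to_dict(self) -> dict:
        return {
            "matches": self.matches,
            "studies_per_region": self.studies_per_region,
            "matched_count": self.matched_count,
            "unmatched_fraction": self.unmatched_fraction,
        }


def match_external(
    unique: CNVRSet, external: CNVRSet, min_ro: float = 0.5
) -> ExternalMatchReport:
    """Match each query region against catalogue regions at >= min_ro RO."""
    report = ExternalMatchReport()
    ext_by_chrom: dict[str, list[CNVR]] = {}
    for r in external.regions:
        ext_by_chrom.setdefault(r.chrom, []).append(r)
    for lst in ext_by_chrom.values():
        lst.sort(key=lambda r: (r.start, r.end))
    n_matched = 0
    for q in sorted(
        unique.regions, key=lambda r: (chrom_sort_key(r.chrom), r.start)
    ):
        hits, studies = [], set()
        for e in ext_by_chrom.get(q.chrom, ()):
            if e.start > q.end:
                break
            if reciprocal_overlap(q, e) >= min_ro:
                hits.append(e.region_id)
                studies |= set(e.provenance)
        if hits:
            n_matched += 1
            report.matches[q.region_id] = hits
            report.studies_per_region[q.region_id] = sorted(studies)
    report.matched_count = n_matched
    report.unmatched_fraction = (
        1.0 - n_matched / len(unique.regions) if unique.regions else 1.0
    )
    return report
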