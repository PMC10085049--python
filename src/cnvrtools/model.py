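"""Core domain types for multi-platform CNV consensus analysis.

All genomic coordinates in this package are 1-based and inclusive at both
ends (the convention shared by VCF, CNVnator tables and PennCNV rawcnv
output); conversion to BED's 0-based half-open coordinates happens only at
the file boundary in :mod:`cnvrtools.call_io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

#: Bovine autosome labels; CNV detection is restricted to autosomes.
DEFAULT_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 30))


class CNVType(str, enum.Enum):
    """Type of an individual copy-number call."""

    DEL = "DEL"
    DUP = "DUP"


class CNVRType(str, enum.Enum):
    """Type of a copy-number-variation region (aggregate of calls).

    A region is COMPLEX when both deletion and duplication calls
    contributed to it.
    """

    DELETION = "DELETION"
    DUPLICATION = "DUPLICATION"
    COMPLEX = "COMPLEX"


class Source(str, enum.Enum):
    """Caller/platform that produced a CNV call."""

    CNVNATOR = "CNVNATOR"
    DELLY = "DELLY"
    PENNCNV = "PENNCNV"


class SetKind(str, enum.Enum):
    """Provenance class of a CNVR set."""

    SEQ = "SEQ"
    GEN = "GEN"
    POP = "POP"
    ANI = "ANI"
    UNIQUE = "UNIQUE"
    EXTERNAL = "EXTERNAL"


def normalize_chrom(token: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix and return the bare label."""
    token = token.strip()
    if token.lower().startswith("chr"):
        token = token[3:]
    return token


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Sort numeric chromosome labels numerically, others lexically after."""
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


@dataclass(frozen=True)
class CNVCall:
    """One caller-emitted copy-number variant for one sample.

    Quality fields are source-specific: ``p_value``/``q0`` for CNVnator,
    ``pe_support`` for DELLY, ``num_snps`` for PennCNV. ``record_key``
    groups DELLY calls that came from the same multi-sample VCF record.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: CNVType
    source: Source
    p_value: Optional[float] = None
    q0: Optional[float] = None
    pe_support: Optional[int] = None
    num_snps: Optional[int] = None
    copy_number: Optional[int] = None
    record_key: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleQC:
    """Per-sample SNP-array QC summary: LRR SD, BAF drift, waviness factor."""

    sample_id: str
    lrr_sd: float
    baf_drift: float
    waviness_factor: float


@dataclass
class CNVR:
    """A genomic region aggregating overlapping CNV calls.

    ``carriers`` is the union of member sample ids; ``frequency`` is the
    carrier fraction of an explicitly supplied cohort size (never inferred).
    ``provenance`` records contributing sources or source-set tags.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    cnvr_type: CNVRType
    members: list = field(default_factory=list)
    carriers: frozenset[str] = frozenset()
    frequency: Optional[float] = None
    provenance: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"CNVR end ({self.end}) < start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CNVRSet:
    """A named, provenance-tagged collection of CNVRs sorted by position."""

    name: str
    kind: SetKind
    regions: list[CNVR] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(
            self.regions, key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end)
        )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


@dataclass
class TruthCNV:
    """A simulated true CNV locus with population frequency and carriers."""

    locus_id: str
    chrom: str
    start: int
    end: int
    cnv_type: CNVType
    pop_frequency: float
    carriers: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomicFeature:
    """A gene, pseudogene or QTL interval used for overlap annotation."""

    chrom: str
    start: int
    end: int
    feature_id: str
    category: str  # GENE | PSEUDOGENE | QTL
    subcategory: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("feature end < start")


@dataclass(frozen=True)
class ExternalCNVR:
    """A CNVR from an external catalogue (DGVa-style), with study id."""

    chrom: str
    start: int
    end: int
    cnv_type: str  # DEL | DUP | COMPLEX | UNKNOWN
    study_id: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("external CNVR end < start")


def sort_regions(regions: Iterable) -> list:
    """Sort interval-like objects by (chromosome, start, end)."""
    return sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end))
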