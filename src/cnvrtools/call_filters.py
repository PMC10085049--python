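"""Per-caller retention criteria applied to raw CNV call lists.

All filters only drop calls, never modify them, so output is always a
subset of the input and filtering is idempotent.

Defaults:

* size window 1 kb - 5 Mb, inclusive on both ends (the smallest retained
  read-pair call in practice is exactly 1,000 bp, so the bound behaves
  inclusively);
* CNVnator: e-value p < 0.05 and fraction of zero-mapping-quality reads
  q0 < 0.5;
* DELLY: paired-end support from more than four read pairs (>= 5);
* PennCNV: >= 10 markers per call, after dropping whole samples whose
  array QC fails (LRR SD <= 0.30, BAF drift <= 0.01, |waviness| <= 0.05).
"""

from __future__ import annotations

import enum
import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import yaml

from .model import CNVCall, SampleQC, Source


@dataclass
class FilterConfig:
    """Thresholds for all per-caller retention rules."""

    min_size_bp: int = 1_000
    max_size_bp: int = 5_000_000
    cnvnator_max_p: float = 0.05
    cnvnator_max_q0: float = 0.5
    delly_min_pe: int = 5
    penncnv_min_snps: int = 10
    penncnv_strict_gt_snps: bool = False  # require num_snps strictly > threshold
    lrr_sd_max: float = 0.30
    baf_drift_max: float = 0.01
    wf_max: float = 0.05
    exclude_delly_singletons: bool = False

    def __post_init__(self) -> None:
        if self.min_size_bp >= self.max_size_bp:
            raise ValueError("min_size_bp must be < max_size_bp")
        for name in (
            "cnvnator_max_p", "cnvnator_max_q0", "lrr_sd_max",
            "baf_drift_max", "wf_max",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class CallLabel(str, enum.Enum):
    POPULATIONAL = "POPULATIONAL"
    SINGLETON = "SINGLETON"


def _size_ok(call: CNVCall, cfg: FilterConfig) -> bool:
    return cfg.min_size_bp <= call.length <= cfg.max_size_bp


def filter_cnvnator(
    calls: Sequence[CNVCall], cfg: Optional[FilterConfig] = None
) -> list[CNVCall]:
    """Retain read-depth calls in the size window with p < max_p, q0 < max_q0."""
    cfg = cfg or FilterConfig()
    out = []
    for c in calls:
        if c.p_value is None or c.q0 is None:
            raise ValueError(
                f"CNVnator call {c.chrom}:{c.start}-{c.end} ({c.sample_id}) "
                "is missing p_value or q0"
            )
        if (
            _size_ok(c, cfg)
            and c.p_value < cfg.cnvnator_max_p
            and c.q0 < cfg.cnvnator_max_q0
        ):
            out.append(c)
    return out


def filter_delly(
    calls: Sequence[CNVCall], cfg: Optional[FilterConfig] = None
) -> list[CNVCall]:
    """Retain paired-end/split-read calls in the size window with PE >= min.

    If ``cfg.exclude_delly_singletons`` is set, calls whose VCF record had a
    single carrier are also dropped.
    """
    cfg = cfg or FilterConfig()
    labels = label_populational(calls) if cfg.exclude_delly_singletons else {}
    out = []
    for c in calls:
        if c.pe_support is None:
            raise ValueError(
                f"DELLY call {c.chrom}:{c.start}-{c.end} ({c.sample_id}) "
                "is missing pe_support"
            )
        if not (_size_ok(c, cfg) and c.pe_support >= cfg.delly_min_pe):
            continue
        if cfg.exclude_delly_singletons and labels.get(c) == CallLabel.SINGLETON:
            continue
        out.append(c)
    return out


def label_populational(calls: Sequence[CNVCall]) -> dict[CNVCall, CallLabel]:
    """Label each call POPULATIONAL (record has >= 2 carriers) or SINGLETON.

    Calls originating from the same VCF record share a ``record_key``; a
    call without a record key is its own record.
    """
    carriers_per_record: dict[str, set[str]] = {}
    for c in calls:
        key = c.record_key or f"{c.chrom}:{c.start}-{c.end}:{c.sample_id}"
        carriers_per_record.setdefault(key, set()).add(c.sample_id)
    labels = {}
    for c in calls:
        key = c.record_key or f"{c.chrom}:{c.start}-{c.end}:{c.sample_id}"
        labels[c] = (
            CallLabel.POPULATIONAL
            if len(carriers_per_record[key]) >= 2
            else CallLabel.SINGLETON
        )
    return labels


def passing_qc_samples(
    qc: Sequence[SampleQC], cfg: Optional[FilterConfig] = None
) -> set[str]:
    """Samples whose array QC summary passes all three thresholds.

    The waviness factor is compared by absolute value (it can be negative).
    """
    cfg = cfg or FilterConfig()
    return {
        r.sample_id
        for r in qc
        if r.lrr_sd <= cfg.lrr_sd_max
        and r.baf_drift <= cfg.baf_drift_max
        and abs(r.waviness_factor) <= cfg.wf_max
    }


def filter_penncnv(
    calls: Sequence[CNVCall],
    qc: Sequence[SampleQC],
    cfg: Optional[FilterConfig] = None,
) -> list[CNVCall]:
    """Drop calls from QC-failing samples, then apply marker/size rules.

    QC (LRR SD, BAF drift, waviness) is sample-scoped: a failing sample
    loses all of its calls. Remaining calls need ``num_snps`` at or above
    the marker threshold (strictly above with ``penncnv_strict_gt_snps``)
    and a length in the size window.
    """
    cfg = cfg or FilterConfig()
    qc_samples = {r.sample_id for r in qc}
    missing = {c.sample_id for c in calls} - qc_samples
    if missing:
        raise ValueError(
            f"samples with calls but no QC row: {sorted(missing)}"
        )
    good = passing_qc_samples(qc, cfg)
    out = []
    for c in calls:
        if c.sample_id not in good:
            continue
        if c.num_snps is None:
            raise ValueError(
                f"PennCNV call {c.chrom}:{c.start}-{c.end} ({c.sample_id}) "
                "is missing num_snps"
            )
        snp_ok = (
            c.num_snps > cfg.penncnv_min_snps
            if cfg.penncnv_strict_gt_snps
            else c.num_snps >= cfg.penncnv_min_snps
        )
        if snp_ok and _size_ok(c, cfg):
            out.append(c)
    return out


def filter_calls(
    calls: Sequence[CNVCall],
    cfg: Optional[FilterConfig] = None,
    qc: Optional[Sequence[SampleQC]] = None,
) -> list[CNVCall]:
    """Dispatch a homogeneous call list to the filter for its source."""
    if not calls:
        return []
    sources = {c.source for c in calls}
    if len(sources) != 1:
        raise ValueError(f"mixed sources in one filter pass: {sources}")
    src = sources.pop()
    if src == Source.CNVNATOR:
        return filter_cnvnator(calls, cfg)
    if src == Source.DELLY:
        return filter_delly(calls, cfg)
    return filter_penncnv(calls, qc or [], cfg)
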