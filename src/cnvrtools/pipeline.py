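"""End-to-end orchestration: filter -> build sets -> merge -> compare/annotate.

Stages run in a fixed order with per-stage count logging; any stage error
aborts with a stage-named message. Outputs carry no timestamps, so
re-running with the same config and inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import annotate as annotate_mod
from . import call_io
from . import external as external_mod
from .builder import (
    BuildReport,
    build_cnvr_ani,
    build_cnvr_gen,
    build_cnvr_pop,
    build_cnvr_seq,
    build_unique_set,
)
from .call_filters import (
    FilterConfig,
    filter_cnvnator,
    filter_delly,
    filter_penncnv,
)
from .model import DEFAULT_AUTOSOMES, CNVCall, SetKind, Source

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run, loadable from YAML."""

    cnvnator_dir: str = ""
    delly_vcf: str = ""
    penncnv_rawcnv: str = ""
    sample_qc: str = ""
    dual_samples: str = ""  # file with one sample id per line; empty = infer
    out_dir: str = "cnvr_out"
    external_catalogue: str = ""  # optional TSV
    features_bed: str = ""  # optional BED6+
    filters: FilterConfig = field(default_factory=FilterConfig)
    min_ro: float = 0.5
    min_freq: float = 0.05
    frequency_denominator: Optional[int] = None  # None = QC-passing count
    autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.min_ro <= 1):
            raise ConfigError("min_ro must be in (0, 1]")
        if not (0 <= self.min_freq <= 1):
            raise ConfigError("min_freq must be in [0, 1]")
        if self.frequency_denominator is not None and self.frequency_denominator <= 0:
            raise ConfigError("frequency_denominator must be positive")
        for name in ("cnvnator_dir", "delly_vcf", "penncnv_rawcnv", "sample_qc"):
            p = getattr(self, name)
            if not p:
                raise ConfigError(f"{name} is required")
            if not Path(p).exists():
                raise ConfigError(f"{name}: {p} does not exist")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["autosomes"] = list(self.autosomes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        filters = data.pop("filters", {}) or {}
        if "autosomes" in data:
            data["autosomes"] = tuple(str(c) for c in data["autosomes"])
        try:
            return cls(filters=FilterConfig(**filters), **data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _read_cnvnator_dir(
    cnvnator_dir, autosomes: Sequence[str]
) -> dict[str, list[CNVCall]]:
    """One CNVnator table per sequenced sample; sample id from filename."""
    by_sample: dict[str, list[CNVCall]] = {}
    files = sorted(Path(cnvnator_dir).glob("*.cnvnator.txt"))
    if not files:
        files = sorted(Path(cnvnator_dir).glob("*.txt"))
    for p in files:
        sample = p.name.split(".")[0]
        by_sample[sample] = call_io.read_cnvnator_calls(
            p, sample_id=sample, autosomes=autosomes
        )
    return by_sample


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full consensus pipeline; returns a result dict.

    Writes each set as BED + JSON, a BuildReport JSON, the effective
    config, and a count log into ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    report = BuildReport()
    cfg_f = config.filters

    # --- stage: read inputs
    try:
        cnvnator_by_sample = _read_cnvnator_dir(
            config.cnvnator_dir, config.autosomes
        )
        delly_calls = call_io.read_delly_vcf(
            config.delly_vcf, autosomes=config.autosomes
        )
        penncnv_calls = call_io.read_penncnv_rawcnv(
            config.penncnv_rawcnv, autosomes=config.autosomes
        )
        qc = call_io.read_sample_qc(config.sample_qc)
    except Exception as exc:
        raise StageError("read_inputs", exc) from exc
    cnvnator_calls = [c for cs in cnvnator_by_sample.values() for c in cs]
    report.input_calls = {
        "CNVNATOR": len(cnvnator_calls),
        "DELLY": len(delly_calls),
        "PENNCNV": len(penncnv_calls),
    }
    log(f"input calls: {report.input_calls}")

    # --- stage: filter
    try:
        cnvnator_f = filter_cnvnator(cnvnator_calls, cfg_f)
        delly_f = filter_delly(delly_calls, cfg_f)
        penncnv_f = filter_penncnv(penncnv_calls, qc, cfg_f)
    except Exception as exc:
        raise StageError("filter", exc) from exc
    report.retained_calls = {
        "CNVNATOR": len(cnvnator_f),
        "DELLY": len(delly_f),
        "PENNCNV": len(penncnv_f),
    }
    log(f"retained calls: {report.retained_calls}")

    # --- stage: build_seq / build_gen
    try:
        seq = build_cnvr_seq(cnvnator_f, delly_f, min_ro=config.min_ro)
        gen = build_cnvr_gen(penncnv_f)
    except Exception as exc:
        raise StageError("build_seq_gen", exc) from exc
    report.record_set("SEQ", seq)
    report.record_set("GEN", gen)
    log(f"CNVR_SEQ: {len(seq)} regions; CNVR_GEN: {len(gen)} regions")

    # --- stage: build_pop
    from .call_filters import passing_qc_samples

    denominator = config.frequency_denominator
    if denominator is None:
        denominator = len(passing_qc_samples(qc, cfg_f))
        log(f"frequency denominator inferred from QC-passing samples: {denominator}")
    try:
        pop = build_cnvr_pop(
            gen, seq, n_individuals=denominator,
            min_freq=config.min_freq, min_ro=config.min_ro,
        )
    except Exception as exc:
        raise StageError("build_pop", exc) from exc
    report.record_set("POP", pop)
    log(f"CNVR_POP: {len(pop)} regions (min_freq={config.min_freq})")

    # --- stage: build_ani
    try:
        if config.dual_samples:
            dual = [
                s for s in Path(config.dual_samples).read_text().split()
                if s
            ]
        else:
            penncnv_samples = {c.sample_id for c in penncnv_f}
            dual = sorted(set(cnvnator_by_sample) & penncnv_samples)
            log(f"dual-platform samples inferred: {len(dual)}")
        penncnv_by_sample: dict[str, list[CNVCall]] = {}
        for c in penncnv_f:
            penncnv_by_sample.setdefault(c.sample_id, []).append(c)
        cnvnator_f_by_sample: dict[str, list[CNVCall]] = {}
        for c in cnvnator_f:
            cnvnator_f_by_sample.setdefault(c.sample_id, []).append(c)
        ani = build_cnvr_ani(
            penncnv_by_sample, cnvnator_f_by_sample, dual, min_ro=config.min_ro
        )
    except Exception as exc:
        raise StageError("build_ani", exc) from exc
    report.record_set("ANI", ani)
    log(f"CNVR_ANI: {len(ani)} regions from {len(dual)} dual-platform samples")

    # --- stage: build_unique
    try:
        unique, shared = build_unique_set(pop, ani)
    except Exception as exc:
        raise StageError("build_unique", exc) from exc
    report.record_set("UNIQUE", unique)
    report.shared_pop_ani = shared
    log(
        f"CNVR_UNIQUE: {len(unique)} regions "
        f"(|POP|={len(pop)} + |ANI|={len(ani)} - shared={shared})"
    )

    # --- stage: write sets
    sets = {"seq": seq, "gen": gen, "pop": pop, "ani": ani, "unique": unique}
    for name, cnvr_set in sets.items():
        call_io.write_cnvr_bed(cnvr_set, out_dir / f"cnvr_{name}.bed")
        call_io.write_cnvr_json(cnvr_set, out_dir / f"cnvr_{name}.json")

    result: dict = {
        "sets": sets,
        "report": report,
        "shared_pop_ani": shared,
        "out_dir": out_dir,
    }

    # --- optional stage: external comparison
    if config.external_catalogue:
        try:
            raw = call_io.read_external_catalogue(config.external_catalogue)
            ext_set = external_mod.build_external_set(raw)
            ext_report = external_mod.match_external(
                unique, ext_set, min_ro=config.min_ro
            )
        except Exception as exc:
            raise StageError("compare_external", exc) from exc
        with open(out_dir / "external_report.json", "w") as fh:
            json.dump(ext_report.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        log(
            f"external comparison: {ext_report.matched_count}/{len(unique)} "
            f"matched (catalogue: {len(ext_set)} merged regions)"
        )
        result["external_report"] = ext_report

    # --- optional stage: annotation
    if config.features_bed:
        try:
            feats = call_io.read_feature_bed(config.features_bed)
            overlaps = annotate_mod.overlap_features(unique, feats)
            summary = annotate_mod.summarize_annotation(overlaps)
        except Exception as exc:
            raise StageError("annotate", exc) from exc
        annotate_mod.write_annotation_tsv(overlaps, out_dir / "annotation.tsv")
        with open(out_dir / "annotation_summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        log(
            f"annotation: {summary.n_regions_annotated}/{summary.n_regions_total}"
            f" regions carry genes ({summary.pct_regions_annotated}%)"
        )
        result["annotation_summary"] = summary

    with open(out_dir / "build_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    config.to_yaml(out_dir / "effective_config.yaml")
    (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return result
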