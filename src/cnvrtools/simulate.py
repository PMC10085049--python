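"""Call-level simulation of a CNV study with known truth.

The generator emulates the input level of the pipeline — caller output
files, not reads or array intensities. It draws a landscape of true CNV
loci on a synthetic diploid autosomal genome, assigns carriers per
individual from each locus's population frequency, and emits three
caller-style outputs (read-depth table, paired-end SV VCF, array rawcnv)
with platform-specific false positives, false negatives, breakpoint jitter
and call splitting.

Study design defaults mirror a typical dual-platform cattle cohort:
547 array-genotyped individuals passing QC, 38 whole-genome-sequenced,
36 of them with both data types. The default genome is five synthetic
autosomes of 50 Mb (large enough for hundreds of loci, small enough for
sub-minute runs).

False positives are drawn independently per platform — the assumption
under which cross-platform consensus improves precision. Splitting emits
two fragments sharing one boundary base so a >= 1 bp merge can rejoin
them. Array marker counts are deterministic in the emitted call length
(one marker per ``marker_spacing_bp``), so platform detectability is
predictable from the truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import call_io
from .model import CNVCall, CNVType, SampleQC, Source, TruthCNV

DEFAULT_GENOME: tuple[tuple[str, int], ...] = tuple(
    (str(i), 50_000_000) for i in range(1, 6)
)


@dataclass(frozen=True)
class CallerNoiseModel:
    """Noise behaviour of one caller/platform."""

    fp_rate_per_mb: float = 0.0
    fn_rate: float = 0.0
    breakpoint_jitter_sd_bp: float = 0.0
    split_prob: float = 0.0
    min_detectable_bp: int = 0
    size_bias: float = 1.0
    fp_size_log_median: float = 8_000.0
    fp_size_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.fp_rate_per_mb < 0 or not 0 <= self.fn_rate <= 1:
            raise ValueError("invalid noise rates")
        if self.breakpoint_jitter_sd_bp < 0 or not 0 <= self.split_prob <= 1:
            raise ValueError("invalid jitter/split parameters")


@dataclass(frozen=True)
class NoisePreset:
    """Per-caller noise models plus the array marker spacing."""

    name: str
    cnvnator: CallerNoiseModel
    delly: CallerNoiseModel
    penncnv: CallerNoiseModel
    marker_spacing_bp: int = 3_430  # high-density bovine array mean spacing


ZERO_NOISE = NoisePreset(
    name="zero",
    cnvnator=CallerNoiseModel(),
    delly=CallerNoiseModel(),
    penncnv=CallerNoiseModel(),
    marker_spacing_bp=1_000,
)

#: Moderate, realistic noise: WGS callers are sensitive but false-positive
#: prone; the array caller is sparse, conservative and coarse-breakpointed.
MODERATE = NoisePreset(
    name="moderate",
    cnvnator=CallerNoiseModel(
        fp_rate_per_mb=0.6, fn_rate=0.10, breakpoint_jitter_sd_bp=300.0,
        split_prob=0.05, min_detectable_bp=1_000,
    ),
    delly=CallerNoiseModel(
        fp_rate_per_mb=0.4, fn_rate=0.15, breakpoint_jitter_sd_bp=150.0,
        split_prob=0.02, min_detectable_bp=1_000,
    ),
    penncnv=CallerNoiseModel(
        fp_rate_per_mb=0.04, fn_rate=0.20, breakpoint_jitter_sd_bp=2_000.0,
        min_detectable_bp=20_000,
        fp_size_log_median=60_000.0, fp_size_log_sd=0.6,
    ),
)

#: Heavier WGS false-positive load reproducing the qualitative platform
#: disparity (WGS callers emitting orders of magnitude more calls per
#: animal than the array caller).
HEAVY_WGS = NoisePreset(
    name="heavy_wgs",
    cnvnator=CallerNoiseModel(
        fp_rate_per_mb=8.0, fn_rate=0.10, breakpoint_jitter_sd_bp=300.0,
        split_prob=0.05, min_detectable_bp=1_000,
    ),
    delly=CallerNoiseModel(
        fp_rate_per_mb=2.0, fn_rate=0.15, breakpoint_jitter_sd_bp=150.0,
        split_prob=0.02, min_detectable_bp=1_000,
    ),
    penncnv=CallerNoiseModel(
        fp_rate_per_mb=0.02, fn_rate=0.20, breakpoint_jitter_sd_bp=2_000.0,
        min_detectable_bp=20_000,
        fp_size_log_median=60_000.0, fp_size_log_sd=0.6,
    ),
)

PRESETS: dict[str, NoisePreset] = {
    p.name: p for p in (ZERO_NOISE, MODERATE, HEAVY_WGS)
}


@dataclass(frozen=True)
class StudyDesign:
    """Cohort structure: who is genotyped, sequenced, or both."""

    n_genotyped: int = 547
    n_sequenced: int = 38
    n_dual: int = 36

    def __post_init__(self) -> None:
        if self.n_dual > min(self.n_genotyped, self.n_sequenced):
            raise ValueError("n_dual cannot exceed either cohort size")

    @property
    def genotyped(self) -> list[str]:
        return [f"GIR{i:04d}" for i in range(1, self.n_genotyped + 1)]

    @property
    def dual(self) -> list[str]:
        return self.genotyped[: self.n_dual]

    @property
    def sequenced(self) -> list[str]:
        extra = self.n_sequenced - self.n_dual
        return self.dual + [f"SEQ{i:04d}" for i in range(1, extra + 1)]

    @property
    def all_samples(self) -> list[str]:
        return self.genotyped + self.sequenced[self.n_dual:]


def simulate_truth(
    genome: Sequence[tuple[str, int]] = DEFAULT_GENOME,
    n_loci: int = 80,
    size_log_median: float = 30_000.0,
    size_log_sd: float = 1.2,
    size_range: tuple[int, int] = (1_000, 5_000_000),
    type_probs: Optional[dict[CNVType, float]] = None,
    freq_range: tuple[float, float] = (0.01, 0.5),
    min_gap_bp: int = 10_000,
    seed: int = 0,
) -> list[TruthCNV]:
    """Draw non-overlapping true CNV loci on a synthetic genome.

    Sizes are log-normal (median ``size_log_median``, log-sd
    ``size_log_sd``) truncated to ``size_range``; population frequencies
    are log-uniform on ``freq_range`` so rare loci dominate but common
    (> 30%) loci occur. Loci are separated by at least ``min_gap_bp`` so
    that distinct loci never merge under the >= 1 bp rule.
    """
    rng = np.random.default_rng(seed)
    type_probs = type_probs or {CNVType.DEL: 0.65, CNVType.DUP: 0.35}
    types, probs = zip(*sorted(type_probs.items(), key=lambda kv: kv[0].value))
    lo_f, hi_f = freq_range
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome}
    chrom_labels = [c for c, _ in genome]
    chrom_lengths = dict(genome)
    loci: list[TruthCNV] = []
    attempts = 0
    max_attempts = max(10_000, n_loci * 200)
    while len(loci) < n_loci:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_loci} loci on the given genome "
                f"(placed {len(loci)}); genome too small for the size "
                "distribution and gap requirement"
            )
        size = int(
            round(rng.lognormal(math.log(size_log_median), size_log_sd))
        )
        size = min(max(size, size_range[0]), size_range[1])
        weights = np.array([chrom_lengths[c] for c in chrom_labels], float)
        chrom = chrom_labels[rng.choice(len(chrom_labels), p=weights / weights.sum())]
        clen = chrom_lengths[chrom]
        if size >= clen:
            continue
        start = int(rng.integers(1, clen - size + 1))
        end = start + size - 1
        ok = all(
            end + min_gap_bp < s or start - min_gap_bp > e
            for s, e in occupied[chrom]
        )
        if not ok:
            continue
        occupied[chrom].append((start, end))
        freq = float(
            math.exp(rng.uniform(math.log(lo_f), math.log(hi_f)))
        )
        cnv_type = types[int(rng.choice(len(types), p=np.array(probs) / sum(probs)))]
        loci.append(
            TruthCNV(
                locus_id=f"L{len(loci) + 1:04d}",
                chrom=chrom,
                start=start,
                end=end,
                cnv_type=cnv_type,
                pop_frequency=freq,
            )
        )
    loci.sort(key=lambda t: (int(t.chrom) if t.chrom.isdigit() else 99, t.start))
    return [
        replace_locus_id(t, f"L{i + 1:04d}") for i, t in enumerate(loci)
    ]


def replace_locus_id(t: TruthCNV, new_id: str) -> TruthCNV:
    return TruthCNV(
        locus_id=new_id, chrom=t.chrom, start=t.start, end=t.end,
        cnv_type=t.cnv_type, pop_frequency=t.pop_frequency, carriers=t.carriers,
    )


def assign_carriers(
    truth: Sequence[TruthCNV], samples: Sequence[str], seed: int = 0
) -> list[TruthCNV]:
    """Each sample carries each locus independently with its frequency."""
    rng = np.random.default_rng(seed)
    out = []
    for t in truth:
        draws = rng.random(len(samples))
        carriers = frozenset(
            s for s, d in zip(samples, draws) if d < t.pop_frequency
        )
        out.append(
            TruthCNV(
                locus_id=t.locus_id, chrom=t.chrom, start=t.start, end=t.end,
                cnv_type=t.cnv_type, pop_frequency=t.pop_frequency,
                carriers=carriers,
            )
        )
    return out


def _jitter_interval(
    start: int, end: int, sd: float, chrom_len: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Gaussian endpoint jitter, truncated to chromosome bounds, non-inverted."""
    if sd > 0:
        start = start + int(round(rng.normal(0, sd)))
        end = end + int(round(rng.normal(0, sd)))
    start = max(1, min(start, chrom_len))
    end = max(1, min(end, chrom_len))
    if end < start:
        start, end = end, start
    if end == start:
        end = min(start + 1, chrom_len)
    return start, end


def _maybe_split(
    start: int, end: int, split_prob: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Split a call into two fragments sharing one boundary base."""
    if split_prob > 0 and end - start > 2 and rng.random() < split_prob:
        mid = int(rng.integers(start + 1, end))
        return [(start, mid), (mid, end)]
    return [(start, end)]


def _apply_size_bias(
    start: int, end: int, bias: float, chrom_len: int
) -> tuple[int, int]:
    if bias == 1.0:
        return start, end
    length = end - start + 1
    new_len = max(2, int(round(length * bias)))
    centre = (start + end) // 2
    s = max(1, centre - new_len // 2)
    e = min(chrom_len, s + new_len - 1)
    return s, e


def _fp_intervals(
    model: CallerNoiseModel,
    genome: Sequence[tuple[str, int]],
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Uniformly scattered false-positive intervals for one sample."""
    total_mb = sum(l for _, l in genome) / 1e6
    n_fp = int(rng.poisson(model.fp_rate_per_mb * total_mb))
    chroms = [c for c, _ in genome]
    lengths = dict(genome)
    weights = np.array([lengths[c] for c in chroms], float)
    weights /= weights.sum()
    out = []
    for _ in range(n_fp):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        clen = lengths[chrom]
        size = int(round(rng.lognormal(
            math.log(model.fp_size_log_median), model.fp_size_log_sd
        )))
        size = min(max(size, 1_000), min(5_000_000, clen - 1))
        start = int(rng.integers(1, clen - size + 1))
        out.append((chrom, start, start + size - 1))
    return out


def simulate_calls(
    truth: Sequence[TruthCNV],
    design: StudyDesign,
    preset: NoisePreset = MODERATE,
    genome: Sequence[tuple[str, int]] = DEFAULT_GENOME,
    seed: int = 0,
) -> tuple[dict[Source, list[CNVCall]], list[dict]]:
    """Generate in-memory caller outputs for a carrier-assigned truth set.

    Returns ``(calls_by_source, delly_records)`` where ``delly_records``
    are dicts suitable for :func:`cnvrtools.call_io.write_delly_vcf`
    (DELLY is a joint caller: one record per variant with all carriers).
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = dict(genome)
    sequenced = design.sequenced
    genotyped = design.genotyped
    calls: dict[Source, list[CNVCall]] = {
        Source.CNVNATOR: [], Source.DELLY: [], Source.PENNCNV: [],
    }
    delly_records: list[dict] = []

    # --- read-depth caller: per sequenced sample, per carried locus
    m = preset.cnvnator
    for sample in sequenced:
        for t in truth:
            if sample not in t.carriers or t.length < m.min_detectable_bp:
                continue
            if rng.random() < m.fn_rate:
                continue
            clen = chrom_lengths[t.chrom]
            s, e = _apply_size_bias(t.start, t.end, m.size_bias, clen)
            s, e = _jitter_interval(s, e, m.breakpoint_jitter_sd_bp, clen, rng)
            for fs, fe in _maybe_split(s, e, m.split_prob, rng):
                calls[Source.CNVNATOR].append(CNVCall(
                    sample_id=sample, chrom=t.chrom, start=fs, end=fe,
                    cnv_type=t.cnv_type, source=Source.CNVNATOR,
                    p_value=float(rng.uniform(1e-8, 0.04)),
                    q0=float(rng.uniform(0.0, 0.45)),
                ))
        for chrom, fs, fe in _fp_intervals(m, genome, rng):
            calls[Source.CNVNATOR].append(CNVCall(
                sample_id=sample, chrom=chrom, start=fs, end=fe,
                cnv_type=CNVType.DEL if rng.random() < 0.65 else CNVType.DUP,
                source=Source.CNVNATOR,
                p_value=float(rng.uniform(1e-8, 0.04)),
                q0=float(rng.uniform(0.0, 0.45)),
            ))

    # --- paired-end caller: one joint record per variant across samples
    m = preset.delly
    for t in truth:
        if t.length < m.min_detectable_bp:
            continue
        detected = [
            s for s in sequenced
            if s in t.carriers and rng.random() >= m.fn_rate
        ]
        if not detected:
            continue
        clen = chrom_lengths[t.chrom]
        s, e = _apply_size_bias(t.start, t.end, m.size_bias, clen)
        s, e = _jitter_interval(s, e, m.breakpoint_jitter_sd_bp, clen, rng)
        delly_records.append({
            "chrom": t.chrom, "start": s, "end": e,
            "svtype": t.cnv_type.value,
            "pe": int(5 + rng.poisson(8)),
            "carriers": set(detected),
        })
    for sample in sequenced:  # platform-independent FP records (singletons)
        for chrom, fs, fe in _fp_intervals(m, genome, rng):
            delly_records.append({
                "chrom": chrom, "start": fs, "end": fe,
                "svtype": "DEL" if rng.random() < 0.7 else "DUP",
                "pe": int(5 + rng.poisson(8)),
                "carriers": {sample},
            })
    delly_records.sort(key=lambda r: (
        int(r["chrom"]) if r["chrom"].isdigit() else 99, r["start"], r["end"]
    ))
    for idx, rec in enumerate(delly_records):
        key = f"{rec['chrom']}:{rec['start']}:{rec['svtype']}:{idx}"
        for sample in sorted(rec["carriers"]):
            calls[Source.DELLY].append(CNVCall(
                sample_id=sample, chrom=rec["chrom"], start=rec["start"],
                end=rec["end"], cnv_type=CNVType(rec["svtype"]),
                source=Source.DELLY, pe_support=rec["pe"], record_key=key,
            ))

    # --- array caller: per genotyped sample; marker count fixes detectability
    m = preset.penncnv
    spacing = preset.marker_spacing_bp
    for sample in genotyped:
        for t in truth:
            if sample not in t.carriers or t.length < m.min_detectable_bp:
                continue
            if rng.random() < m.fn_rate:
                continue
            clen = chrom_lengths[t.chrom]
            s, e = _apply_size_bias(t.start, t.end, m.size_bias, clen)
            s, e = _jitter_interval(s, e, m.breakpoint_jitter_sd_bp, clen, rng)
            num_snps = max(1, round((e - s + 1) / spacing))
            if num_snps < 3:  # the array HMM needs a minimum marker run
                continue
            calls[Source.PENNCNV].append(CNVCall(
                sample_id=sample, chrom=t.chrom, start=s, end=e,
                cnv_type=t.cnv_type, source=Source.PENNCNV,
                num_snps=num_snps,
                copy_number=1 if t.cnv_type == CNVType.DEL else 3,
            ))
        for chrom, fs, fe in _fp_intervals(m, genome, rng):
            num_snps = max(1, round((fe - fs + 1) / spacing))
            if num_snps < 3:
                continue
            cnv_type = CNVType.DEL if rng.random() < 0.6 else CNVType.DUP
            calls[Source.PENNCNV].append(CNVCall(
                sample_id=sample, chrom=chrom, start=fs, end=fe,
                cnv_type=cnv_type, source=Source.PENNCNV,
                num_snps=num_snps,
                copy_number=1 if cnv_type == CNVType.DEL else 3,
            ))
    return calls, delly_records


def make_sample_qc(
    design: StudyDesign, seed: int = 0, n_failing: int = 0
) -> list[SampleQC]:
    """QC rows for all genotyped samples; optionally the last n fail LRR SD."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, sample in enumerate(design.genotyped):
        fail = i >= design.n_genotyped - n_failing
        rows.append(SampleQC(
            sample_id=sample,
            lrr_sd=float(rng.uniform(0.35, 0.5)) if fail
            else float(rng.uniform(0.05, 0.28)),
            baf_drift=float(rng.uniform(0.0, 0.008)),
            waviness_factor=float(rng.uniform(-0.04, 0.04)),
        ))
    return rows


def write_truth_table(truth: Sequence[TruthCNV], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\ttype\tfrequency\tcarriers\n")
        for t in truth:
            fh.write(
                f"{t.locus_id}\t{t.chrom}\t{t.start}\t{t.end}\t"
                f"{t.cnv_type.value}\t{t.pop_frequency:.6g}\t"
                f"{','.join(sorted(t.carriers))}\n"
            )


def read_truth_table(path) -> list[TruthCNV]:
    out = []
    with open(path) as fh:
        fh.readline()
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            out.append(TruthCNV(
                locus_id=f[0], chrom=f[1], start=int(f[2]), end=int(f[3]),
                cnv_type=CNVType(f[4]), pop_frequency=float(f[5]),
                carriers=frozenset(f[6].split(",")) if f[6] else frozenset(),
            ))
    return out


def emit_caller_files(
    truth: Sequence[TruthCNV],
    design: StudyDesign,
    preset: NoisePreset,
    out_dir,
    genome: Sequence[tuple[str, int]] = DEFAULT_GENOME,
    seed: int = 0,
    n_failing_qc: int = 0,
) -> dict[str, Path]:
    """Write all caller-format files plus the truth table into ``out_dir``.

    Layout: ``cnvnator/<sample>.cnvnator.txt`` per sequenced sample,
    ``delly.vcf``, ``penncnv.rawcnv``, ``sample_qc.tsv``, cohort sample
    lists and ``truth.tsv``. Identical seeds yield byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls, delly_records = simulate_calls(
        truth, design, preset, genome=genome, seed=seed
    )
    paths: dict[str, Path] = {}

    cnvnator_dir = out_dir / "cnvnator"
    cnvnator_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list[CNVCall]] = {s: [] for s in design.sequenced}
    for c in calls[Source.CNVNATOR]:
        by_sample[c.sample_id].append(c)
    for sample in design.sequenced:
        p = cnvnator_dir / f"{sample}.cnvnator.txt"
        ordered = sorted(
            by_sample[sample],
            key=lambda c: (int(c.chrom) if c.chrom.isdigit() else 99, c.start, c.end),
        )
        call_io.write_cnvnator_calls(ordered, p)
    paths["cnvnator_dir"] = cnvnator_dir

    paths["delly_vcf"] = out_dir / "delly.vcf"
    call_io.write_delly_vcf(
        delly_records, design.sequenced, list(genome), paths["delly_vcf"]
    )

    paths["penncnv_rawcnv"] = out_dir / "penncnv.rawcnv"
    ordered = sorted(
        calls[Source.PENNCNV],
        key=lambda c: (c.sample_id, int(c.chrom) if c.chrom.isdigit() else 99,
                       c.start, c.end),
    )
    call_io.write_penncnv_rawcnv(ordered, paths["penncnv_rawcnv"])

    paths["sample_qc"] = out_dir / "sample_qc.tsv"
    call_io.write_sample_qc(
        make_sample_qc(design, seed=seed, n_failing=n_failing_qc),
        paths["sample_qc"],
    )

    for name, samples in (
        ("samples_genotyped.txt", design.genotyped),
        ("samples_sequenced.txt", design.sequenced),
        ("samples_dual.txt", design.dual),
    ):
        p = out_dir / name
        p.write_text("\n".join(samples) + "\n")
        paths[name.rsplit(".", 1)[0]] = p

    paths["truth"] = out_dir / "truth.tsv"
    write_truth_table(truth, paths["truth"])
    return paths


def simulate_study(
    seed: int,
    preset: NoisePreset = MODERATE,
    design: Optional[StudyDesign] = None,
    genome: Sequence[tuple[str, int]] = DEFAULT_GENOME,
    n_loci: int = 80,
    size_log_median: float = 80_000.0,
    size_log_sd: float = 0.7,
    size_range: tuple[int, int] = (40_000, 1_000_000),
    freq_range: tuple[float, float] = (0.01, 0.5),
) -> tuple[list[TruthCNV], dict[Source, list[CNVCall]], list[dict], StudyDesign]:
    """Convenience wrapper: truth + carriers + in-memory caller outputs.

    Truth sizes default to the array-detectable regime (log-normal median
    80 kb truncated to [40 kb, 1 Mb]) — the regime the dual-platform
    consensus method targets: an array call needs >= 10 markers to survive
    filtering, which at the default 3.43 kb marker spacing means loci below
    ~34 kb are structurally invisible to the array caller.
    """
    design = design or StudyDesign()
    truth = simulate_truth(
        genome=genome, n_loci=n_loci, size_log_median=size_log_median,
        size_log_sd=size_log_sd, size_range=size_range,
        freq_range=freq_range, seed=seed,
    )
    truth = assign_carriers(truth, design.all_samples, seed=seed + 1)
    calls, delly_records = simulate_calls(
        truth, design, preset, genome=genome, seed=seed + 2
    )
    return truth, calls, delly_records, design
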