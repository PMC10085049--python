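"""Readers and writers for every on-disk format the pipeline touches.

Parsers normalize everything into :class:`~cnvrtools.model.CNVCall` with
1-based inclusive coordinates. BED output is converted to 0-based half-open
at this boundary and converted back on read. Chromosome labels are
normalized by stripping a leading ``chr``; by default only autosome labels
1-29 (bovine) are accepted and calls on other contigs are dropped (and
counted when a ``counts`` dict is supplied).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional, Sequence

import pysam

from .model import (
    CNVR,
    CNVRSet,
    CNVRType,
    CNVCall,
    CNVType,
    DEFAULT_AUTOSOMES,
    ExternalCNVR,
    GenomicFeature,
    SampleQC,
    SetKind,
    Source,
    normalize_chrom,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


_COORD_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _parse_coord(token: str, path, line_no: int) -> tuple[str, int, int]:
    m = _COORD_RE.match(token)
    if not m:
        raise ParseError(
            f"{path}:{line_no}: malformed coordinate token {token!r}"
        )
    return (
        normalize_chrom(m.group("chrom")),
        int(m.group("start")),
        int(m.group("end")),
    )


def _chrom_ok(chrom: str, autosomes: Sequence[str]) -> bool:
    return chrom in autosomes


# ---------------------------------------------------------------------------
# CNVnator table
# ---------------------------------------------------------------------------

_CNVNATOR_TYPES = {"deletion": CNVType.DEL, "duplication": CNVType.DUP}


def read_cnvnator_calls(
    path,
    sample_id: str,
    e_value_column: int = 0,
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES,
    counts: Optional[dict] = None,
) -> list[CNVCall]:
    """Parse a CNVnator call table into CNVCalls for one sample.

    Columns: type, chrom:start-end, size, normalized RD, four e-values, q0.
    ``e_value_column`` (0-3) selects which of the four e-values populates
    ``p_value``; CNVnator reports several test variants and published
    workflows differ in which one they threshold, so the choice is exposed.
    """
    if not 0 <= e_value_column <= 3:
        raise ValueError("e_value_column must be in 0..3")
    calls: list[CNVCall] = []
    skipped_chrom = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 9:
                raise ParseError(
                    f"{path}:{line_no}: expected >=9 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            type_token = fields[0].lower()
            if type_token not in _CNVNATOR_TYPES:
                raise ParseError(
                    f"{path}:{line_no}: unknown CNV type token {fields[0]!r}"
                )
            chrom, start, end = _parse_coord(fields[1], path, line_no)
            if not _chrom_ok(chrom, autosomes):
                skipped_chrom += 1
                continue
            calls.append(
                CNVCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=_CNVNATOR_TYPES[type_token],
                    source=Source.CNVNATOR,
                    p_value=float(fields[4 + e_value_column]),
                    q0=float(fields[8]),
                )
            )
    if counts is not None:
        counts["skipped_non_autosomal"] = counts.get(
            "skipped_non_autosomal", 0
        ) + skipped_chrom
    return calls


def write_cnvnator_calls(calls: Sequence[CNVCall], path) -> None:
    """Write calls in CNVnator's native table layout (inverse of the reader).

    The selected e-value is written into all four e-value columns; the
    normalized-RD column is written as 0.5 for deletions and 1.5 for
    duplications (a nominal diploid-relative depth).
    """
    with open(path, "w") as fh:
        for c in calls:
            type_token = "deletion" if c.cnv_type == CNVType.DEL else "duplication"
            rd = 0.5 if c.cnv_type == CNVType.DEL else 1.5
            p = c.p_value if c.p_value is not None else 0.0
            q0 = c.q0 if c.q0 is not None else 0.0
            fh.write(
                f"{type_token}\t{c.chrom}:{c.start}-{c.end}\t{c.length}\t"
                f"{rd}\t{p:g}\t{p:g}\t{p:g}\t{p:g}\t{q0:g}\n"
            )


# ---------------------------------------------------------------------------
# DELLY-style SV VCF
# ---------------------------------------------------------------------------

def read_delly_vcf(
    path,
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES,
    counts: Optional[dict] = None,
) -> list[CNVCall]:
    """Parse a DELLY-style SV VCF into one CNVCall per (record, carrier).

    A carrier is any sample whose genotype contains at least one ALT allele;
    missing genotypes (./.) are non-carriers. Records with SVTYPE other than
    DEL/DUP are skipped and counted, as are records lacking INFO/END.
    Calls from the same record share a ``record_key`` so that
    populational/singleton labelling can recover per-record carrier counts.
    """
    skipped_svtype = 0
    skipped_no_end = 0
    skipped_chrom = 0
    calls: list[CNVCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ParseError(f"{path}: VCF has no sample columns")
        for idx, rec in enumerate(vcf):
            svtype = rec.info.get("SVTYPE")
            if svtype not in ("DEL", "DUP"):
                skipped_svtype += 1
                continue
            start = rec.pos  # pysam .pos is 1-based
            # pysam folds INFO/END into .stop; without END, stop collapses
            # onto the padding-base span (end <= pos for a symbolic ALT)
            end = int(rec.stop)
            if end <= start:
                logger.warning(
                    "%s: record %s has no INFO/END; skipped", path, rec.id or idx
                )
                skipped_no_end += 1
                continue
            chrom = normalize_chrom(rec.chrom)
            if not _chrom_ok(chrom, autosomes):
                skipped_chrom += 1
                continue
            pe = int(rec.info.get("PE", 0))
            record_key = f"{chrom}:{start}:{svtype}:{idx}"
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None:
                    continue
                alleles = [a for a in gt if a is not None]
                if any(a > 0 for a in alleles):
                    calls.append(
                        CNVCall(
                            sample_id=sample,
                            chrom=chrom,
                            start=start,
                            end=end,
                            cnv_type=CNVType(svtype),
                            source=Source.DELLY,
                            pe_support=pe,
                            record_key=record_key,
                        )
                    )
    if counts is not None:
        counts["skipped_svtype"] = counts.get("skipped_svtype", 0) + skipped_svtype
        counts["skipped_missing_end"] = (
            counts.get("skipped_missing_end", 0) + skipped_no_end
        )
        counts["skipped_non_autosomal"] = (
            counts.get("skipped_non_autosomal", 0) + skipped_chrom
        )
    return calls


def write_delly_vcf(
    records: Sequence[dict],
    samples: Sequence[str],
    contigs: Sequence[tuple[str, int]],
    path,
) -> None:
    """Write a minimal DELLY-style SV VCF.

    Each record dict needs: chrom, start, end, svtype ('DEL'/'DUP'),
    pe (int), carriers (set of sample ids). Carriers are written 0/1,
    non-carriers 0/0.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=PE,Number=1,Type=Integer,Description="Paired-end support">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
    ]
    for chrom, length in contigs:
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for i, rec in enumerate(records, start=1):
        gts = "\t".join(
            "0/1" if s in rec["carriers"] else "0/0" for s in samples
        )
        lines.append(
            f"{rec['chrom']}\t{rec['start']}\tSV{i:05d}\tN\t<{rec['svtype']}>\t"
            f".\tPASS\tSVTYPE={rec['svtype']};END={rec['end']};PE={rec['pe']}\t"
            f"GT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PennCNV rawcnv
# ---------------------------------------------------------------------------

_RAWCNV_RE = re.compile(
    r"^(?P<coord>\S+)\s+numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state\d+,cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
)


def read_penncnv_rawcnv(
    path,
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES,
    counts: Optional[dict] = None,
) -> list[CNVCall]:
    """Parse a PennCNV rawcnv file into CNVCalls.

    cn < 2 maps to DEL, cn > 2 to DUP; a cn=2 line is copy-neutral and is
    rejected as a format violation. A numsnp/length vs coordinate
    inconsistency only warns (PennCNV lengths count marker-to-marker span).
    """
    calls: list[CNVCall] = []
    skipped_chrom = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            m = _RAWCNV_RE.match(line)
            if not m:
                raise ParseError(f"{path}:{line_no}: unparseable rawcnv line")
            chrom, start, end = _parse_coord(m.group("coord"), path, line_no)
            cn = int(m.group("cn"))
            if cn == 2:
                raise ParseError(
                    f"{path}:{line_no}: cn=2 is copy-neutral, not a CNV"
                )
            stated_len = int(m.group("length").replace(",", ""))
            if stated_len != end - start + 1:
                logger.warning(
                    "%s:%d: stated length %d != coordinate span %d",
                    path, line_no, stated_len, end - start + 1,
                )
            if not _chrom_ok(chrom, autosomes):
                skipped_chrom += 1
                continue
            calls.append(
                CNVCall(
                    sample_id=m.group("sample"),
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=CNVType.DEL if cn < 2 else CNVType.DUP,
                    source=Source.PENNCNV,
                    num_snps=int(m.group("numsnp")),
                    copy_number=cn,
                )
            )
    if counts is not None:
        counts["skipped_non_autosomal"] = (
            counts.get("skipped_non_autosomal", 0) + skipped_chrom
        )
    return calls


def write_penncnv_rawcnv(calls: Sequence[CNVCall], path) -> None:
    """Write calls in PennCNV rawcnv layout (inverse of the reader)."""
    with open(path, "w") as fh:
        for c in calls:
            cn = c.copy_number
            if cn is None:
                cn = 1 if c.cnv_type == CNVType.DEL else 3
            state = {0: 1, 1: 2, 3: 5, 4: 6}.get(cn, 5)
            fh.write(
                f"chr{c.chrom}:{c.start}-{c.end} numsnp={c.num_snps or 0} "
                f"length={c.length:,} state{state},cn={cn} {c.sample_id} "
                f"startsnp=snp_a endsnp=snp_b\n"
            )


# ---------------------------------------------------------------------------
# Sample QC table
# ---------------------------------------------------------------------------

def read_sample_qc(path) -> list[SampleQC]:
    """Read a tab-separated QC table: sample_id, lrr_sd, baf_drift, wf."""
    rows: list[SampleQC] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        required = {"sample_id", "lrr_sd", "baf_drift", "wf"}
        if not required.issubset(header):
            raise ParseError(
                f"{path}: QC table header must contain {sorted(required)}"
            )
        col = {name: header.index(name) for name in header}
        for line_no, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            rows.append(
                SampleQC(
                    sample_id=f[col["sample_id"]],
                    lrr_sd=float(f[col["lrr_sd"]]),
                    baf_drift=float(f[col["baf_drift"]]),
                    waviness_factor=float(f[col["wf"]]),
                )
            )
    return rows


def write_sample_qc(rows: Sequence[SampleQC], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlrr_sd\tbaf_drift\twf\n")
        for r in rows:
            fh.write(
                f"{r.sample_id}\t{r.lrr_sd:g}\t{r.baf_drift:g}\t"
                f"{r.waviness_factor:g}\n"
            )


# ---------------------------------------------------------------------------
# BED (CNVR sets and features)
# ---------------------------------------------------------------------------

def write_cnvr_bed(cnvr_set: CNVRSet, path) -> None:
    """Write a CNVR set as BED6+: 0-based half-open, id, type, carriers, freq.

    Columns: chrom, start-1, end, region_id, cnvr_type, carrier_count,
    frequency (``.`` if unset), provenance (comma-joined, ``.`` if empty).
    """
    with open(path, "w") as fh:
        for r in cnvr_set.regions:
            freq = f"{r.frequency:.6g}" if r.frequency is not None else "."
            prov = ",".join(sorted(r.provenance)) if r.provenance else "."
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\t"
                f"{r.cnvr_type.value}\t{len(r.carriers)}\t{freq}\t{prov}\n"
            )


def read_cnvr_bed(path, kind: SetKind = SetKind.UNIQUE, name: str = "") -> CNVRSet:
    """Read a CNVR BED written by :func:`write_cnvr_bed` back losslessly.

    Carrier identities are not stored in BED, so carriers are reconstructed
    as anonymous placeholders preserving the carrier count.
    """
    regions: list[CNVR] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start_bed, end_bed = int(f[1]), int(f[2])
            if end_bed <= start_bed:
                raise ParseError(
                    f"{path}:{line_no}: BED end ({end_bed}) <= start ({start_bed})"
                )
            n_carriers = int(f[5]) if len(f) > 5 else 0
            freq = None
            if len(f) > 6 and f[6] != ".":
                freq = float(f[6])
            prov = frozenset()
            if len(f) > 7 and f[7] != ".":
                prov = frozenset(f[7].split(","))
            regions.append(
                CNVR(
                    region_id=f[3],
                    chrom=normalize_chrom(f[0]),
                    start=start_bed + 1,
                    end=end_bed,
                    cnvr_type=CNVRType(f[4]),
                    carriers=frozenset(
                        f"{f[3]}_carrier{i}" for i in range(n_carriers)
                    ),
                    frequency=freq,
                    provenance=prov,
                )
            )
    return CNVRSet(name=name or Path(str(path)).stem, kind=kind, regions=regions)


def read_feature_bed(path) -> list[GenomicFeature]:
    """Read features from BED6+: chrom, start, end, id, category, subcategory."""
    feats: list[GenomicFeature] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start_bed, end_bed = int(f[1]), int(f[2])
            if end_bed <= start_bed:
                raise ParseError(
                    f"{path}:{line_no}: BED end ({end_bed}) <= start ({start_bed})"
                )
            feats.append(
                GenomicFeature(
                    chrom=normalize_chrom(f[0]),
                    start=start_bed + 1,
                    end=end_bed,
                    feature_id=f[3] if len(f) > 3 else f"feature{line_no}",
                    category=f[4] if len(f) > 4 else "GENE",
                    subcategory=f[5] if len(f) > 5 else "",
                )
            )
    return feats


# ---------------------------------------------------------------------------
# Intermediate formats: normalized calls TSV and lossless CNVR-set JSON
# ---------------------------------------------------------------------------

_CALL_COLUMNS = (
    "sample_id", "chrom", "start", "end", "type", "source",
    "p_value", "q0", "pe_support", "num_snps", "copy_number", "record_key",
)


def write_calls_tsv(calls: Sequence[CNVCall], path) -> None:
    """Write normalized calls (any source) as a TSV for stage hand-off."""
    def fmt(v):
        return "." if v is None else (f"{v:g}" if isinstance(v, float) else str(v))

    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write("\t".join([
                c.sample_id, c.chrom, str(c.start), str(c.end),
                c.cnv_type.value, c.source.value,
                fmt(c.p_value), fmt(c.q0), fmt(c.pe_support),
                fmt(c.num_snps), fmt(c.copy_number), c.record_key or ".",
            ]) + "\n")


def read_calls_tsv(path) -> list[CNVCall]:
    """Read a normalized calls TSV written by :func:`write_calls_tsv`."""
    calls: list[CNVCall] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != list(_CALL_COLUMNS):
            raise ParseError(f"{path}: unexpected calls TSV header")
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            opt = lambda v, cast: None if v == "." else cast(v)  # noqa: E731
            calls.append(CNVCall(
                sample_id=f[0], chrom=f[1], start=int(f[2]), end=int(f[3]),
                cnv_type=CNVType(f[4]), source=Source(f[5]),
                p_value=opt(f[6], float), q0=opt(f[7], float),
                pe_support=opt(f[8], int), num_snps=opt(f[9], int),
                copy_number=opt(f[10], int),
                record_key=None if f[11] == "." else f[11],
            ))
    return calls


def write_cnvr_json(cnvr_set: CNVRSet, path) -> None:
    """Lossless CNVR-set serialization (keeps carrier identities)."""
    import json

    data = {
        "name": cnvr_set.name,
        "kind": cnvr_set.kind.value,
        "regions": [
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "type": r.cnvr_type.value,
                "carriers": sorted(r.carriers),
                "frequency": r.frequency,
                "provenance": sorted(r.provenance),
            }
            for r in cnvr_set.regions
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_cnvr_json(path) -> CNVRSet:
    import json

    with open(path) as fh:
        data = json.load(fh)
    regions = [
        CNVR(
            region_id=r["region_id"],
            chrom=r["chrom"],
            start=r["start"],
            end=r["end"],
            cnvr_type=CNVRType(r["type"]),
            carriers=frozenset(r["carriers"]),
            frequency=r["frequency"],
            provenance=frozenset(r["provenance"]),
        )
        for r in data["regions"]
    ]
    return CNVRSet(name=data["name"], kind=SetKind(data["kind"]), regions=regions)


def read_external_catalogue(path) -> list[ExternalCNVR]:
    """Read an external CNVR catalogue TSV: chrom, start, end, type, study.

    Coordinates are 1-based inclusive (header required). Assembly mixing is
    the caller's responsibility to have resolved (e.g. via liftover).
    """
    rows: list[ExternalCNVR] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        required = {"chrom", "start", "end", "type", "study"}
        if not required.issubset(header):
            raise ParseError(
                f"{path}: external catalogue header must contain {sorted(required)}"
            )
        col = {name: header.index(name) for name in header}
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            rows.append(
                ExternalCNVR(
                    chrom=normalize_chrom(f[col["chrom"]]),
                    start=int(f[col["start"]]),
                    end=int(f[col["end"]]),
                    cnv_type=f[col["type"]].upper(),
                    study_id=f[col["study"]],
                )
            )
    return rows

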