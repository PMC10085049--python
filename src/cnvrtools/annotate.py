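"""Overlap of CNVR with gene/pseudogene/QTL intervals and summary counting.

Overlap is >= 1 bp by default, on whole feature spans (exon-level
resolution is available simply by supplying exon sub-intervals as
features). Percentages are count/total x 100 rounded to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .intervals import overlap_bp
from .model import CNVRSet, GenomicFeature


@dataclass
class AnnotationOverlaps:
    """Region -> features and feature -> regions maps."""

    region_features: dict[str, list[str]] = field(default_factory=dict)
    feature_regions: dict[str, list[str]] = field(default_factory=dict)
    features_by_id: dict[str, GenomicFeature] = field(default_factory=dict)
    region_types: dict[str, str] = field(default_factory=dict)
    n_regions_total: int = 0


def overlap_features(
    cnvr_set: CNVRSet,
    features: Sequence[GenomicFeature],
    min_overlap_bp: int = 1,
) -> AnnotationOverlaps:
    """Map each region to the features it overlaps by >= min_overlap_bp."""
    out = AnnotationOverlaps(n_regions_total=len(cnvr_set.regions))
    feats_by_chrom: dict[str, list[GenomicFeature]] = {}
    for f in features:
        feats_by_chrom.setdefault(f.chrom, []).append(f)
        out.features_by_id[f.feature_id] = f
    for lst in feats_by_chrom.values():
        lst.sort(key=lambda f: (f.start, f.end))
    for r in cnvr_set.regions:
        out.region_types[r.region_id] = r.cnvr_type.value
        hits = []
        for f in feats_by_chrom.get(r.chrom, ()):
            if f.start > r.end:
                break
            if overlap_bp(r.start, r.end, f.start, f.end) >= min_overlap_bp:
                hits.append(f.feature_id)
        if hits:
            out.region_features[r.region_id] = sorted(hits)
            for fid in hits:
                out.feature_regions.setdefault(fid, []).append(r.region_id)
    for fid in out.feature_regions:
        out.feature_regions[fid].sort()
    return out


def _pct(count: int, total: int) -> float:
    return round(count / total * 100, 2) if total else 0.0


@dataclass
class AnnotationSummary:
    """Counting conventions for an annotated CNVR set."""

    n_regions_total: int = 0
    n_regions_annotated: int = 0
    pct_regions_annotated: float = 0.0
    n_genes: int = 0
    n_pseudogenes: int = 0
    n_regions_with_qtl: int = 0
    pct_regions_with_qtl: float = 0.0
    n_qtl: int = 0
    qtl_by_class: dict[str, int] = field(default_factory=dict)
    qtl_class_pct: dict[str, float] = field(default_factory=dict)
    qtl_by_region_type: dict[str, int] = field(default_factory=dict)
    qtl_region_type_pct: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(vars(self))


def summarize_annotation(overlaps: AnnotationOverlaps) -> AnnotationSummary:
    """Summarize gene/pseudogene/QTL overlap counts and percentages.

    A QTL overlapping several regions is counted once per (QTL, region)
    pair for the by-region-type breakdown but once overall, mirroring the
    convention of reporting distinct QTL with their trait classes.
    """
    s = AnnotationSummary(n_regions_total=overlaps.n_regions_total)
    gene_region_ids: set[str] = set()
    qtl_region_ids: set[str] = set()
    genes: set[str] = set()
    pseudo: set[str] = set()
    qtl: set[str] = set()
    for fid, regions in overlaps.feature_regions.items():
        feat = overlaps.features_by_id[fid]
        cat = feat.category.upper()
        if cat == "QTL":
            qtl.add(fid)
            qtl_region_ids.update(regions)
        else:
            gene_region_ids.update(regions)
            (pseudo if cat == "PSEUDOGENE" else genes).add(fid)
    s.n_genes = len(genes)
    s.n_pseudogenes = len(pseudo)
    s.n_regions_annotated = len(gene_region_ids)
    s.pct_regions_annotated = _pct(s.n_regions_annotated, s.n_regions_total)
    s.n_regions_with_qtl = len(qtl_region_ids)
    s.pct_regions_with_qtl = _pct(s.n_regions_with_qtl, s.n_regions_total)
    s.n_qtl = len(qtl)
    for fid in sorted(qtl):
        feat = overlaps.features_by_id[fid]
        klass = feat.subcategory or "unclassified"
        s.qtl_by_class[klass] = s.qtl_by_class.get(klass, 0) + 1
        for rid in overlaps.feature_regions[fid]:
            rtype = overlaps.region_types.get(rid, "UNKNOWN")
            s.qtl_by_region_type[rtype] = s.qtl_by_region_type.get(rtype, 0) + 1
    s.qtl_class_pct = {k: _pct(v, s.n_qtl) for k, v in s.qtl_by_class.items()}
    total_type = sum(s.qtl_by_region_type.values())
    s.qtl_region_type_pct = {
        k: _pct(v, total_type) for k, v in s.qtl_by_region_type.items()
    }
    return s


def write_annotation_tsv(overlaps: AnnotationOverlaps, path) -> None:
    """Write per-region feature lists: region, type, genes, QTL + classes."""
    with open(path, "w") as fh:
        fh.write("region_id\tregion_type\tgenes\tqtl\tqtl_classes\n")
        for rid in sorted(overlaps.region_features):
            feats = overlaps.region_features[rid]
            genes, qtls, classes = [], [], []
            for fid in feats:
                f = overlaps.features_by_id[fid]
                if f.category.upper() == "QTL":
                    qtls.append(fid)
                    if f.subcategory:
                        classes.append(f.subcategory)
                else:
                    genes.append(fid)
            fh.write(
                f"{rid}\t{overlaps.region_types.get(rid, '.')}\t"
                f"{','.join(genes) or '.'}\t{','.join(qtls) or '.'}\t"
                f"{','.join(sorted(set(classes))) or '.'}\n"
            )
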