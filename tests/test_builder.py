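"""Consensus set construction: SEQ, GEN, POP, ANI and the unique union."""

from __future__ import annotations

import pytest

from conftest import make_call, make_region, random_intervals
from oracles import brute_force_merge

from cnvrtools.builder import (
    SetSummary,
    build_cnvr_ani,
    build_cnvr_gen,
    build_cnvr_pop,
    build_cnvr_seq,
    build_unique_set,
)
from cnvrtools.model import CNVRSet, CNVRType, CNVType, SetKind, Source


class TestBuildSeq:
    def test_cross_caller_match_spans_union(self):
        rd = [make_call(start=1000, end=2000, sample_id="A")]
        pe = [make_call(start=1400, end=2400, source=Source.DELLY, sample_id="B")]
        seq = build_cnvr_seq(rd, pe)
        (region,) = seq.regions
        assert (region.start, region.end) == (1000, 2400)
        assert region.cnvr_type == CNVRType.DELETION
        assert region.carriers == {"A", "B"}
        assert region.provenance == {"CNVNATOR", "DELLY"}

    def test_unmatched_regions_excluded(self):
        rd = [
            make_call(start=1000, end=2000),
            make_call(chrom="2", start=50_000, end=60_000),
        ]
        pe = [make_call(start=1400, end=2400, source=Source.DELLY)]
        seq = build_cnvr_seq(rd, pe)
        assert len(seq) == 1 and seq.regions[0].chrom == "1"

    def test_opposite_types_make_complex(self):
        rd = [make_call(start=1000, end=2000, cnv_type=CNVType.DEL)]
        pe = [make_call(start=1400, end=2400, cnv_type=CNVType.DUP,
                        source=Source.DELLY)]
        (region,) = build_cnvr_seq(rd, pe).regions
        assert region.cnvr_type == CNVRType.COMPLEX

    def test_empty_caller_input_gives_empty_set(self, caplog):
        seq = build_cnvr_seq([], [make_call(source=Source.DELLY)])
        assert len(seq) == 0 and seq.kind == SetKind.SEQ


class TestBuildGen:
    def test_carriers_pooled_across_samples(self):
        calls = [
            make_call(start=1000, end=3000, source=Source.PENNCNV, sample_id="A"),
            make_call(start=2000, end=4000, source=Source.PENNCNV, sample_id="B"),
        ]
        (region,) = build_cnvr_gen(calls).regions
        assert region.carriers == {"A", "B"}
        assert region.cnvr_type == CNVRType.DELETION

    def test_mixed_types_complex(self):
        calls = [
            make_call(start=1000, end=3000, source=Source.PENNCNV),
            make_call(start=2000, end=4000, source=Source.PENNCNV,
                      cnv_type=CNVType.DUP, sample_id="B"),
        ]
        (region,) = build_cnvr_gen(calls).regions
        assert region.cnvr_type == CNVRType.COMPLEX


class TestBuildPop:
    def _gen_seq(self, gen_carriers, seq_carriers=("X",)):
        gen = CNVRSet("g", SetKind.GEN, [
            make_region("G1", start=1000, end=2000, carriers=gen_carriers),
        ])
        seq = CNVRSet("s", SetKind.SEQ, [
            make_region("S1", start=1200, end=2200, carriers=seq_carriers),
        ])
        return gen, seq

    def test_frequency_gate(self):
        gen, seq = self._gen_seq(("a", "b", "c"))
        pop = build_cnvr_pop(gen, seq, n_individuals=40)
        (region,) = pop.regions  # 4 carriers / 40 = 0.1 >= 0.05
        assert region.frequency == pytest.approx(0.1)
        assert (region.start, region.end) == (1000, 2200)

    def test_rare_region_dropped(self):
        gen, seq = self._gen_seq((), ("x",))
        assert len(build_cnvr_pop(gen, seq, n_individuals=40)) == 0  # 1/40

    def test_no_matches_gives_empty_set(self):
        gen = CNVRSet("g", SetKind.GEN, [make_region("G1", start=1, end=100)])
        seq = CNVRSet("s", SetKind.SEQ, [make_region("S1", start=10_000, end=10_100)])
        assert len(build_cnvr_pop(gen, seq, n_individuals=40)) == 0

    def test_invalid_cohort_size(self):
        gen, seq = self._gen_seq(("a",))
        with pytest.raises(ValueError):
            build_cnvr_pop(gen, seq, n_individuals=0)

    def test_mixed_type_match_is_complex(self):
        gen = CNVRSet("g", SetKind.GEN, [
            make_region("G1", start=1000, end=2000,
                        cnvr_type=CNVRType.DELETION,
                        carriers=tuple(f"c{i}" for i in range(5))),
        ])
        seq = CNVRSet("s", SetKind.SEQ, [
            make_region("S1", start=1100, end=2100,
                        cnvr_type=CNVRType.DUPLICATION, carriers=("x",)),
        ])
        (region,) = build_cnvr_pop(gen, seq, n_individuals=40).regions
        assert region.cnvr_type == CNVRType.COMPLEX


class TestBuildAni:
    def test_cross_platform_pair_retained_and_merged(self):
        penncnv = {"S1": [make_call(start=1000, end=2000,
                                    source=Source.PENNCNV, sample_id="S1")]}
        cnvnator = {"S1": [make_call(start=1200, end=2200, sample_id="S1")]}
        ani = build_cnvr_ani(penncnv, cnvnator, ["S1"])
        (region,) = ani.regions  # RO ~ 0.80 -> both calls kept, span 1000-2200
        assert (region.start, region.end) == (1000, 2200)
        assert region.carriers == {"S1"}

    def test_pooling_across_samples_unions_carriers(self):
        penncnv = {
            "S1": [make_call(start=1000, end=2000, source=Source.PENNCNV,
                             sample_id="S1")],
            "S2": [make_call(start=1800, end=2800, source=Source.PENNCNV,
                             sample_id="S2")],
        }
        cnvnator = {
            "S1": [make_call(start=1200, end=2200, sample_id="S1")],
            "S2": [make_call(start=1900, end=2900, sample_id="S2")],
        }
        ani = build_cnvr_ani(penncnv, cnvnator, ["S1", "S2"])
        (region,) = ani.regions
        assert region.carriers == {"S1", "S2"}

    def test_sample_without_match_contributes_nothing(self):
        penncnv = {"S1": [make_call(start=1000, end=2000,
                                    source=Source.PENNCNV, sample_id="S1")]}
        cnvnator = {"S1": [make_call(start=500_000, end=600_000,
                                     sample_id="S1")]}
        assert len(build_cnvr_ani(penncnv, cnvnator, ["S1"])) == 0

    def test_single_platform_sample_excluded_with_warning(self, caplog):
        penncnv = {"S1": [make_call(source=Source.PENNCNV, sample_id="S1")]}
        with caplog.at_level("WARNING"):
            ani = build_cnvr_ani(penncnv, {}, ["S1"])
        assert len(ani) == 0
        assert any("one platform" in r.message for r in caplog.records)


class TestBuildUnique:
    def test_overlapping_pop_ani_merge_and_count_shared(self):
        pop = CNVRSet("p", SetKind.POP, [make_region("P1", start=1000, end=2000)])
        ani = CNVRSet("a", SetKind.ANI, [make_region("A1", start=1500, end=2500)])
        unique, shared = build_unique_set(pop, ani)
        assert len(unique) == 1 and shared == 1
        (region,) = unique.regions
        assert {"POP", "ANI"} <= region.provenance

    def test_disjoint_sets_concatenate(self):
        pop = CNVRSet("p", SetKind.POP, [
            make_region(f"P{i}", start=10_000 * i, end=10_000 * i + 100)
            for i in (1, 2)
        ])
        ani = CNVRSet("a", SetKind.ANI, [
            make_region(f"A{i}", chrom="2", start=10_000 * i,
                        end=10_000 * i + 100)
            for i in (1, 2, 3)
        ])
        unique, shared = build_unique_set(pop, ani)
        assert len(unique) == 5 and shared == 0
        tags = [
            ("POP" in r.provenance, "ANI" in r.provenance)
            for r in unique.regions
        ]
        assert tags.count((True, False)) == 2
        assert tags.count((False, True)) == 3

    def test_count_identity_against_merge_oracle(self, rng):
        for _ in range(20):
            pop_iv = random_intervals(rng, 10, n_chroms=2, max_pos=50_000,
                                      max_len=2_000)
            ani_iv = random_intervals(rng, 15, n_chroms=2, max_pos=50_000,
                                      max_len=2_000)
            pop = CNVRSet("p", SetKind.POP, merge_regions(pop_iv, "P"))
            ani = CNVRSet("a", SetKind.ANI, merge_regions(ani_iv, "A"))
            unique, shared = build_unique_set(pop, ani)
            all_spans = [
                (r.chrom, r.start, r.end)
                for r in list(pop.regions) + list(ani.regions)
            ]
            assert len(unique) == len(brute_force_merge(all_spans))
            # sharing bounds the count: |U| >= |POP| + |ANI| - 2*shared
            assert len(pop) + len(ani) - 2 * shared <= len(unique)
            assert len(unique) <= len(pop) + len(ani) - shared


def merge_regions(intervals, prefix):
    """Non-overlapping regions from raw intervals (within-set merge)."""
    from cnvrtools.intervals import merge_calls

    calls = [
        make_call(chrom=c, start=s, end=e, sample_id=f"{prefix}{i}")
        for i, (c, s, e) in enumerate(intervals)
    ]
    return merge_calls(calls, id_prefix=prefix)


class TestSetSummary:
    def test_summary_statistics(self):
        s = CNVRSet("x", SetKind.UNIQUE, [
            make_region("R1", start=1, end=100),                 # 100 bp
            make_region("R2", start=1_000, end=1_299,
                        cnvr_type=CNVRType.DUPLICATION),         # 300 bp
            make_region("R3", chrom="2", start=1, end=200,
                        cnvr_type=CNVRType.COMPLEX),             # 200 bp
        ])
        summary = SetSummary.from_set(s)
        assert summary.n_regions == 3
        assert (summary.n_deletion, summary.n_duplication, summary.n_complex) \
            == (1, 1, 1)
        assert summary.mean_size == pytest.approx(200.0)
        assert summary.median_size == 200
        assert (summary.min_size, summary.max_size) == (100, 300)
        assert summary.total_covered_bp == 600

    def test_empty_set_summary_is_all_zero(self):
        summary = SetSummary.from_set(CNVRSet("e", SetKind.UNIQUE, []))
        assert summary.n_regions == 0 and summary.total_covered_bp == 0
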