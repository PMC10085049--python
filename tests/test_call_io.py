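"""Parser/writer contracts: exact coordinates, carrier expansion, round-trips."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_call, make_region

from cnvrtools import call_io
from cnvrtools.call_io import ParseError
from cnvrtools.model import (
    CNVR,
    CNVRSet,
    CNVRType,
    CNVType,
    SampleQC,
    SetKind,
    Source,
)


class TestCnvnatorTable:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "calls.txt"
        p.write_text(
            "deletion\t1:1001-3000\t2000\t0.31\t1.2e-05\t1e-05\t1e-05\t1e-05\t0.10\n"
        )
        (call,) = call_io.read_cnvnator_calls(p, sample_id="S1")
        assert (call.chrom, call.start, call.end) == ("1", 1001, 3000)
        assert call.cnv_type == CNVType.DEL
        assert call.p_value == pytest.approx(1.2e-05)
        assert call.q0 == pytest.approx(0.10)
        assert call.source == Source.CNVNATOR

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert call_io.read_cnvnator_calls(p, "S1") == []

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text(
            "deletion\t1:1001-3000\t2000\t0.3\t1e-5\t1e-5\t1e-5\t1e-5\t0.1\n"
            "deletion\tbroken\t2000\t0.3\t1e-5\t1e-5\t1e-5\t1e-5\t0.1\n"
        )
        with pytest.raises(ParseError, match=":2"):
            call_io.read_cnvnator_calls(p, "S1")

    def test_unknown_type_token_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("inversion\t1:1-100\t100\t0.3\t1e-5\t1e-5\t1e-5\t1e-5\t0.1\n")
        with pytest.raises(ParseError, match="unknown CNV type"):
            call_io.read_cnvnator_calls(p, "S1")

    def test_non_autosomal_calls_dropped_and_counted(self, tmp_path):
        p = tmp_path / "calls.txt"
        p.write_text(
            "deletion\tX:1001-3000\t2000\t0.3\t1e-5\t1e-5\t1e-5\t1e-5\t0.1\n"
            "deletion\tchr2:1001-3000\t2000\t0.3\t1e-5\t1e-5\t1e-5\t1e-5\t0.1\n"
        )
        counts: dict = {}
        calls = call_io.read_cnvnator_calls(p, "S1", counts=counts)
        assert [c.chrom for c in calls] == ["2"]
        assert counts["skipped_non_autosomal"] == 1

    def test_round_trip_random_calls(self, tmp_path, rng):
        calls = []
        for i in range(50):
            start = int(rng.integers(1, 10**6))
            calls.append(make_call(
                chrom=str(rng.integers(1, 30)), start=start,
                end=start + int(rng.integers(0, 10**5)),
                cnv_type=CNVType.DEL if rng.random() < 0.5 else CNVType.DUP,
                sample_id="S1",
                p_value=float(rng.uniform(0, 0.1)),
                q0=float(rng.uniform(0, 1)),
            ))
        p = tmp_path / "rt.txt"
        call_io.write_cnvnator_calls(calls, p)
        back = call_io.read_cnvnator_calls(p, "S1")
        assert [(c.chrom, c.start, c.end, c.cnv_type) for c in back] == [
            (c.chrom, c.start, c.end, c.cnv_type) for c in calls
        ]
        for a, b in zip(calls, back):
            assert b.p_value == pytest.approx(a.p_value, rel=1e-5)
            assert b.q0 == pytest.approx(a.q0, rel=1e-5)


class TestDellyVcf:
    def _write(self, tmp_path, records, samples=("A", "B", "C")):
        p = tmp_path / "sv.vcf"
        call_io.write_delly_vcf(records, list(samples), [("1", 10**7)], p)
        return p

    def test_carrier_expansion(self, tmp_path):
        p = self._write(tmp_path, [{
            "chrom": "1", "start": 5001, "end": 9000,
            "svtype": "DEL", "pe": 7, "carriers": {"A", "C"},
        }])
        calls = call_io.read_delly_vcf(p)
        assert sorted(c.sample_id for c in calls) == ["A", "C"]
        for c in calls:
            assert (c.start, c.end, c.pe_support) == (5001, 9000, 7)
            assert c.cnv_type == CNVType.DEL
        assert len({c.record_key for c in calls}) == 1

    def test_non_cnv_svtype_skipped_and_counted(self, tmp_path):
        p = tmp_path / "sv.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
            '##INFO=<ID=PE,Number=1,Type=Integer,Description="p">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##ALT=<ID=INV,Description="Inversion">\n'
            '##ALT=<ID=DEL,Description="Deletion">\n'
            "##contig=<ID=1,length=10000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\tSV1\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=500;PE=9\tGT\t0/1\n"
            "1\t600\tSV2\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=900;PE=9\tGT\t0/1\n"
        )
        counts: dict = {}
        calls = call_io.read_delly_vcf(p, counts=counts)
        assert len(calls) == 1 and counts["skipped_svtype"] == 1

    def test_missing_end_record_skipped_with_count(self, tmp_path):
        p = tmp_path / "sv.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=PE,Number=1,Type=Integer,Description="p">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##ALT=<ID=DEL,Description="Deletion">\n'
            "##contig=<ID=1,length=10000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\tSV1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;PE=9\tGT\t0/1\n"
        )
        counts: dict = {}
        assert call_io.read_delly_vcf(p, counts=counts) == []
        assert counts["skipped_missing_end"] == 1

    def test_no_carriers_gives_zero_calls(self, tmp_path):
        p = self._write(tmp_path, [{
            "chrom": "1", "start": 100, "end": 900,
            "svtype": "DUP", "pe": 9, "carriers": set(),
        }])
        assert call_io.read_delly_vcf(p) == []

    def test_no_sample_columns_is_an_error(self, tmp_path):
        p = tmp_path / "sv.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            "##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(ParseError, match="no sample columns"):
            call_io.read_delly_vcf(p)

    def test_call_count_equals_total_carriers(self, tmp_path, rng):
        samples = [f"S{i}" for i in range(8)]
        records, total = [], 0
        for i in range(20):
            carriers = {
                s for s in samples if rng.random() < 0.4
            }
            total += len(carriers)
            records.append({
                "chrom": "1", "start": 1000 * (i + 1),
                "end": 1000 * (i + 1) + 500, "svtype": "DEL",
                "pe": 6, "carriers": carriers,
            })
        p = self._write(tmp_path, records, samples)
        assert len(call_io.read_delly_vcf(p)) == total


class TestPennCnvRawcnv:
    def test_known_region_line(self, tmp_path):
        p = tmp_path / "calls.rawcnv"
        p.write_text(
            "chr7:9455783-9693750 numsnp=25 length=237,968 state2,cn=1 "
            "S014 startsnp=rs100 endsnp=rs200\n"
        )
        (call,) = call_io.read_penncnv_rawcnv(p)
        assert (call.chrom, call.start, call.end) == ("7", 9455783, 9693750)
        assert call.cnv_type == CNVType.DEL
        assert call.num_snps == 25
        assert call.sample_id == "S014"

    def test_cn3_is_duplication(self, tmp_path):
        p = tmp_path / "calls.rawcnv"
        p.write_text(
            "chr2:1000-20000 numsnp=12 length=19,001 state5,cn=3 S1 "
            "startsnp=a endsnp=b\n"
        )
        (call,) = call_io.read_penncnv_rawcnv(p)
        assert call.cnv_type == CNVType.DUP and call.copy_number == 3

    def test_copy_neutral_line_rejected(self, tmp_path):
        p = tmp_path / "calls.rawcnv"
        p.write_text(
            "chr2:1000-20000 numsnp=12 length=19,001 state3,cn=2 S1 "
            "startsnp=a endsnp=b\n"
        )
        with pytest.raises(ParseError, match="copy-neutral"):
            call_io.read_penncnv_rawcnv(p)

    def test_round_trip(self, tmp_path, rng):
        calls = []
        for i in range(30):
            start = int(rng.integers(1, 10**6))
            calls.append(make_call(
                chrom=str(rng.integers(1, 30)), start=start,
                end=start + int(rng.integers(10_000, 10**5)),
                cnv_type=CNVType.DEL if rng.random() < 0.5 else CNVType.DUP,
                source=Source.PENNCNV, sample_id=f"S{i}",
                num_snps=int(rng.integers(10, 100)),
            ))
        p = tmp_path / "rt.rawcnv"
        call_io.write_penncnv_rawcnv(calls, p)
        back = call_io.read_penncnv_rawcnv(p)
        assert [
            (c.chrom, c.start, c.end, c.cnv_type, c.num_snps, c.sample_id)
            for c in back
        ] == [
            (c.chrom, c.start, c.end, c.cnv_type, c.num_snps, c.sample_id)
            for c in calls
        ]


class TestCnvrBed:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        region = make_region("CNVR46", chrom="28", start=123251, end=413750)
        s = CNVRSet("u", SetKind.UNIQUE, [region])
        p = tmp_path / "u.bed"
        call_io.write_cnvr_bed(s, p)
        assert p.read_text().startswith("28\t123250\t413750\tCNVR46")

    def test_round_trip_random_regions(self, tmp_path, rng):
        regions = []
        for i in range(100):
            start = int(rng.integers(1, 10**7))
            regions.append(CNVR(
                region_id=f"R{i}", chrom=str(rng.integers(1, 30)),
                start=start, end=start + int(rng.integers(0, 10**6)),
                cnvr_type=list(CNVRType)[int(rng.integers(0, 3))],
                carriers=frozenset(f"c{j}" for j in range(int(rng.integers(0, 5)))),
                frequency=float(np.round(rng.uniform(0, 1), 4)),
                provenance=frozenset({"POP"}),
            ))
        s = CNVRSet("rt", SetKind.POP, regions)
        p = tmp_path / "rt.bed"
        call_io.write_cnvr_bed(s, p)
        back = call_io.read_cnvr_bed(p, kind=SetKind.POP)
        assert [
            (r.chrom, r.start, r.end, r.cnvr_type, len(r.carriers), r.frequency)
            for r in back.regions
        ] == [
            (r.chrom, r.start, r.end, r.cnvr_type, len(r.carriers), r.frequency)
            for r in s.regions
        ]
        # BED length arithmetic: end_bed - start_bed == internal length
        for line, r in zip(p.read_text().splitlines(), s.regions):
            f = line.split("\t")
            assert int(f[2]) - int(f[1]) == r.length

    def test_empty_set_writes_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        call_io.write_cnvr_bed(CNVRSet("e", SetKind.UNIQUE, []), p)
        assert p.read_text() == ""
        assert len(call_io.read_cnvr_bed(p)) == 0

    def test_invalid_bed_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("1\t500\t500\tR1\tDELETION\t0\t.\t.\n")
        with pytest.raises(ParseError, match="end"):
            call_io.read_cnvr_bed(p)


class TestIntermediateFormats:
    def test_calls_tsv_round_trip_all_sources(self, tmp_path):
        calls = [
            make_call(source=Source.CNVNATOR),
            make_call(source=Source.DELLY, record_key="1:5:DEL:0"),
            make_call(source=Source.PENNCNV, copy_number=1),
        ]
        p = tmp_path / "calls.tsv"
        call_io.write_calls_tsv(calls, p)
        assert call_io.read_calls_tsv(p) == calls

    def test_cnvr_json_round_trip(self, tmp_path):
        regions = [
            make_region("R1", carriers=("a", "b"), provenance=("POP",)),
            make_region("R2", chrom="3", start=5, end=10,
                        cnvr_type=CNVRType.COMPLEX),
        ]
        s = CNVRSet("x", SetKind.UNIQUE, regions)
        p = tmp_path / "x.json"
        call_io.write_cnvr_json(s, p)
        back = call_io.read_cnvr_json(p)
        assert back.kind == SetKind.UNIQUE
        assert [
            (r.region_id, r.chrom, r.start, r.end, r.cnvr_type, r.carriers)
            for r in back.regions
        ] == [
            (r.region_id, r.chrom, r.start, r.end, r.cnvr_type, r.carriers)
            for r in s.regions
        ]

    def test_sample_qc_round_trip_and_header_check(self, tmp_path):
        rows = [SampleQC("S1", 0.12, 0.002, -0.01), SampleQC("S2", 0.31, 0.02, 0.06)]
        p = tmp_path / "qc.tsv"
        call_io.write_sample_qc(rows, p)
        back = call_io.read_sample_qc(p)
        assert [r.sample_id for r in back] == ["S1", "S2"]
        assert back[0].waviness_factor == pytest.approx(-0.01)
        bad = tmp_path / "bad.tsv"
        bad.write_text("sample\tlrr\n")
        with pytest.raises(ParseError, match="header"):
            call_io.read_sample_qc(bad)

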