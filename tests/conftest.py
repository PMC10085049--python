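from __future__ import annotations

import numpy as np
import pytest

from cnvrtools.model import CNVR, CNVRType, CNVCall, CNVType, Source


def make_call(
    chrom="1",
    start=1_000,
    end=2_000,
    cnv_type=CNVType.DEL,
    source=Source.CNVNATOR,
    sample_id="S1",
    **quality,
) -> CNVCall:
    """A CNVCall with source-appropriate default quality fields."""
    defaults = {
        Source.CNVNATOR: {"p_value": 1e-4, "q0": 0.1},
        Source.DELLY: {"pe_support": 10},
        Source.PENNCNV: {"num_snps": 20},
    }[source]
    return CNVCall(
        sample_id=sample_id,
        chrom=chrom,
        start=start,
        end=end,
        cnv_type=cnv_type,
        source=source,
        **{**defaults, **quality},
    )


def make_region(
    region_id="R1",
    chrom="1",
    start=1_000,
    end=2_000,
    cnvr_type=CNVRType.DELETION,
    carriers=("S1",),
    provenance=(),
) -> CNVR:
    return CNVR(
        region_id=region_id,
        chrom=chrom,
        start=start,
        end=end,
        cnvr_type=cnvr_type,
        carriers=frozenset(carriers),
        provenance=frozenset(provenance),
    )


def random_intervals(
    rng: np.random.Generator,
    n: int,
    n_chroms: int = 3,
    max_pos: int = 10_000,
    max_len: int = 500,
) -> list[tuple[str, int, int]]:
    """Random (chrom, start, end) tuples for oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = str(rng.integers(1, n_chroms + 1))
        start = int(rng.integers(1, max_pos))
        length = int(rng.integers(1, max_len + 1))
        out.append((chrom, start, start + length - 1))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
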