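"""The interval primitives behind CNVR construction.

Shows the >=1 bp transitive merge (how overlapping calls become one
region), the reciprocal-overlap statistic, and carrier frequency.
"""

from cnvrtools import CNVCall, CNVType, Source, merge_calls, reciprocal_overlap, \
    region_frequency


def call(sample, start, end, cnv_type=CNVType.DEL):
    return CNVCall(sample, "1", start, end, cnv_type, Source.CNVNATOR,
                   p_value=1e-5, q0=0.1)


calls = [
    call("A", 101, 200),
    call("B", 150, 300),                    # chains with the first
    call("C", 180, 250, CNVType.DUP),       # opposite dosage direction
    call("A", 400, 500, CNVType.DUP),       # separate region
]
regions = merge_calls(calls)
for r in regions:
    print(f"{r.region_id}: chr{r.chrom}:{r.start}-{r.end} {r.cnvr_type.value} "
          f"carriers={sorted(r.carriers)}")
# The first three calls overlap transitively -> one region spanning
# 101-300; deletion and duplication members make it COMPLEX.

a, b = regions[0], regions[1]
print(f"reciprocal overlap of the two regions: {reciprocal_overlap(a, b):.2f}")
print(f"carrier frequency of region 1 in a 40-animal cohort: "
      f"{region_frequency(regions[0], 40):.3f}")
# Two regions are 'the same' across callers/platforms/studies when their
# reciprocal overlap (overlap length over each region's length, take the
# minimum) reaches 0.5.
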