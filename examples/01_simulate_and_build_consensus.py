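"""Simulate a dual-platform CNV study and build the consensus CNVR sets.

A cohort of 547 array-genotyped animals (38 sequenced, 36 with both data
types) is simulated with 80 true CNV loci under moderate caller noise; the
pipeline then filters each caller's output and builds the population-level
(POP), per-animal (ANI) and unique consensus region sets.
"""

from cnvrtools import (
    Source,
    build_cnvr_ani,
    build_cnvr_gen,
    build_cnvr_pop,
    build_cnvr_seq,
    build_unique_set,
    filter_cnvnator,
    filter_delly,
    filter_penncnv,
)
from cnvrtools.simulate import MODERATE, make_sample_qc, simulate_study

truth, calls, _, design = simulate_study(seed=1, preset=MODERATE)
qc = make_sample_qc(design, seed=1)

cn = filter_cnvnator(calls[Source.CNVNATOR])
dl = filter_delly(calls[Source.DELLY])
pc = filter_penncnv(calls[Source.PENNCNV], qc)
print(f"calls after filtering: read-depth {len(cn)}, paired-end {len(dl)}, "
      f"array {len(pc)}")

seq = build_cnvr_seq(cn, dl)           # WGS consensus (50% reciprocal overlap)
gen = build_cnvr_gen(pc)               # array regions (>=1 bp merge)
pop = build_cnvr_pop(gen, seq, n_individuals=design.n_genotyped)

by_sample = lambda cs: {s: [c for c in cs if c.sample_id == s]  # noqa: E731
                        for s in {c.sample_id for c in cs}}
ani = build_cnvr_ani(by_sample(pc), by_sample(cn), design.dual)
unique, shared = build_unique_set(pop, ani)

print(f"CNVR_SEQ {len(seq)} | CNVR_GEN {len(gen)} | CNVR_POP {len(pop)} | "
      f"CNVR_ANI {len(ani)}")
print(f"unique high-confidence CNVR: {len(unique)} "
      f"({shared} shared between POP and ANI)")
# POP regions are common variants (carrier frequency >= 5% of the cohort);
# ANI regions were confirmed within single animals on both platforms; their
# union is the final high-confidence catalogue.
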