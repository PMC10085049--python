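# Methods

## Coordinates and interval algebra

All internal coordinates are 1-based and inclusive at both ends, the
convention shared by the three caller formats the package reads (VCF,
CNVnator tables, PennCNV rawcnv); BED's 0-based half-open convention is
converted exactly once, at the file boundary. Overlap lengths therefore use
inclusive arithmetic: `ov = min(endA, endB) − max(startA, startB) + 1`.

Region construction merges calls that overlap by at least `min_overlap_bp`
(default 1) into the connected components of the pairwise overlap graph.
The implementation is a sorted sweep: with starts sorted, an interval joins
the open component iff its start does not exceed the component's maximum
end, which yields exact ≥1 bp components in O(n log n). For thresholds
above 1 bp the ≥1 bp components are refined by exact pairwise union-find,
because a short interval nested under a component's span may overlap no
individual member by ≥ k; the sweep shortcut alone would over-merge. Both
paths are checked against an independent brute-force oracle (explicit
overlap graph + connected components) in the test suite.

Two intervals are considered equivalent across callers, platforms or
studies when their reciprocal overlap `min(ov/len(a), ov/len(b))` reaches
0.5. Matching is many-to-many; consensus construction resolves
multiplicities by transitive clustering of match edges (union-find), in the
same spirit as the ≥1 bp merge. The region reported for a matched cluster
is the span union of its members, so every supporting call is contained;
keep-one-side or intersection variants would be equally defensible, but
span union is the only choice under which the containment invariant
("every member overlaps its region") holds without exceptions.

A consensus region's type is re-derived from all member calls: all-DEL →
DELETION, all-DUP → DUPLICATION, mixed → COMPLEX. This propagates through
every level, so an array deletion matched with a sequencing duplication
yields a COMPLEX high-confidence region.

## Filtering rules and their boundaries

| Rule | Threshold | Boundary behaviour |
|---|---|---|
| call size | 1 kb – 5 Mb | inclusive both ends |
| read-depth e-value | p < 0.05 | strict |
| read-depth q₀ (zero-MQ read fraction) | < 0.5 | strict |
| paired-end support | > 4 read pairs | i.e. ≥ 5 |
| array markers per call | ≥ 10 | `penncnv_strict_gt_snps` switches to > 10 |
| array sample QC | LRR SD ≤ 0.30, BAF drift ≤ 0.01, \|WF\| ≤ 0.05 | inclusive |

The size window is inclusive because the smallest paired-end call that
survives in practice is exactly 1,000 bp. The marker-count rule defaults to
≥ 10 for the same empirical reason (the minimum surviving call has exactly
10 markers). LRR SD, BAF drift and waviness factor are per-sample summary
statistics, so they are applied sample-wise — a failing sample loses all of
its array calls — even though the retention rule is often phrased per call.
The waviness factor is compared by absolute value since it is signed.
Single-carrier ("singleton") paired-end records are labelled but retained
by default; `exclude_delly_singletons` drops them.

Filters never modify calls, so filtering is idempotent, monotone in its
thresholds, and always returns a subset of its input — all three are
property-tested.

## Consensus set definitions

* **CNVR_GEN** — array calls merged at ≥1 bp.
* **CNVR_SEQ** — read-depth and paired-end calls merged per caller at
  ≥1 bp, then clusters of cross-caller matches at RO ≥ 0.5; the span union
  of each cluster is a SEQ region.
* **CNVR_POP** — clusters of GEN×SEQ matches at RO ≥ 0.5; carriers are the
  union over all member calls; regions with carrier frequency ≥ 5% of an
  *explicit* cohort size survive. The denominator is never inferred: which
  cohort (genotyped, sequenced, or both) the "population" means is an
  analysis decision. The pipeline defaults to the number of QC-passing
  genotyped samples, the largest cohort in the dual-platform design.
* **CNVR_ANI** — per dual-platform individual, array×read-depth call pairs
  at RO ≥ 0.5 (type-agnostic; the type is re-derived from members), pooled
  across individuals and merged at ≥1 bp. Only the two per-sample dosage
  signals participate; the joint paired-end caller is population-scoped
  and enters through the POP branch instead.
* **Unique set** — ≥1 bp merge of POP ∪ ANI. Each unique region records
  which source set(s) contributed; the shared count is the number of POP
  regions overlapping any ANI region by ≥1 bp.

## The synthetic study

The generator works at the call level — the pipeline's actual input level —
and does not simulate reads or array intensities. It emulates:

* a diploid autosomal genome, default five 50 Mb autosomes (large enough
  for hundreds of loci, small enough for sub-minute runs);
* true CNV loci: non-overlapping (≥10 kb gap by default, so distinct loci
  never merge), log-normal sizes (generic default median 30 kb, log-sd 1.2,
  truncated to 1 kb–5 Mb), deletion:duplication 65:35, population
  frequencies log-uniform on [0.01, 0.5] so rare loci dominate but >30%
  loci occur;
* a cohort of 547 array-genotyped animals, 38 sequenced, 36 with both —
  each sample carries each locus independently with its frequency;
* three caller outputs with independent noise: per-caller false-positive
  rate per Mb per sample, false-negative rate, Gaussian breakpoint jitter
  (truncated to chromosome bounds, never inverted), call splitting
  (fragments share one boundary base so a ≥1 bp merge can rejoin them),
  and a minimum detectable size. Array marker counts are deterministic in
  the emitted call length (one marker per 3,430 bp by default, the mean
  spacing of a high-density bovine array), so platform detectability is
  predictable from the truth table. Quality fields of both true and
  false-positive calls are drawn so the default filters retain them —
  false positives are caller artifacts that passed the caller's own
  thresholds; removing them is the consensus machinery's job, not the
  filters'.

Noise presets (calibrated once and frozen):

* `zero` — all rates zero, 1 kb marker spacing; callers reproduce truth
  intervals exactly for every carrier.
* `moderate` — WGS callers: 0.6 / 0.4 FP per Mb per sample, 10% / 15%
  misses, 300 / 150 bp jitter; array: 0.04 FP/Mb, 20% misses, 2 kb jitter,
  20 kb minimum size. `simulate_study` pairs this with truth sizes in the
  array-detectable regime (log-normal median 80 kb truncated to
  [40 kb, 1 Mb]): a call needs ≥10 markers to survive filtering, so at
  3.43 kb spacing loci under ~34 kb are structurally invisible to the
  array and can never enter either consensus set. Under this scenario the
  pipeline recovers ≥95% of loci with frequency ≥ 0.1 (96–100% over a
  12-seed survey).
* `heavy_wgs` — the moderate scenario with the WGS false-positive load
  raised (8 / 2 FP per Mb per sample) to reproduce the qualitative
  platform disparity of real studies, where WGS yields hundreds of times
  more calls per animal than the array (the simulated WGS:array call ratio
  on dual-platform animals is ≈250–300, and is an increasing function of
  the WGS noise settings).

Independence of false positives across platforms is the core modelling
assumption — it is exactly what makes cross-platform consensus raise
precision, and it is what the precision property test exercises. Real
platforms share some systematic error sources (GC-rich regions, segmental
duplications), so real-data consensus precision will be lower than the
simulated ≈0.99; the simulation bounds what the *procedure* can do, not
what any dataset will give. Likewise the generator draws carriers
independently per individual (no linkage, no pedigree) and emits exactly
one call per carrier-locus (no multi-allelic dosage), so frequency-based
conclusions transfer only to carrier-presence analyses.

Determinism: every stochastic step flows from one `numpy` generator seeded
by the caller, loci and samples are iterated in fixed order, and no output
file contains a timestamp — identical seeds and configs give byte-identical
files, which is asserted in the acceptance suite.

## Problem sizes used in tests and the acceptance script

Unit and end-to-end tests run reduced designs (e.g. 60 genotyped / 12
sequenced / 10 dual, 30 loci) chosen so the full suite completes in well
under a minute while every code path is exercised; the 20-replicate
precision property uses 120 / 20 / 18 with 40 loci. The acceptance script
runs the full 547 / 38 / 36 design once, plus 10 precision replicates at
the reduced design, a zero-noise exactness check and a heavy-noise
platform-disparity check.

## Numerical and degenerate-input choices

* Frequencies and reciprocal overlaps are exact float ratios; percentages
  in annotation summaries are rounded half-even to two decimals
  (`round(x, 2)`), the convention used for all reported percentages.
* Empty inputs: merging nothing yields an empty set; an empty caller input
  to the sequencing consensus warns and returns an empty SEQ set; an empty
  region set annotates to an all-zero summary; a zero-size cohort is an
  error, never a silent NaN.
* Chromosome labels are normalized by stripping a leading `chr`; only
  configured autosome labels (default 1–29, bovine) pass, and calls on
  other contigs are dropped and counted.
* Ties in region ordering are broken by (chromosome, start, end) with
  numeric chromosome labels sorted numerically; region ids are assigned
  after sorting, so output order and naming are deterministic.
* The CNVnator table carries four e-values; the parser stores the first by
  default and exposes a column-selection option, since published workflows
  differ in which variant they threshold.

## Known limitations

* Cross-assembly comparison requires the user to lift coordinates over
  beforehand; the external-comparison module refuses mixed assembly labels
  but cannot detect unlabelled mismatches.
* Carrier frequency is presence/absence; no copy-number dosage model.
* Exon-level annotation requires exon sub-intervals as input features;
  default operation is on whole gene spans.
* The per-animal consensus requires the same individual to be present on
  both platforms under the same sample id; no sample-matching heuristics
  are attempted.
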