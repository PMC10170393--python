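# Methods

This note documents the models, rules and numerical choices implemented in
`otterdiet`, the defaults they ship with, and what the synthetic-data tests
do and do not demonstrate about real data.

## Read-table filtering

Raw per-marker sample × taxon counts are reduced to presences in two steps.

**Proportional filter.** Within each fecal (and mock) sample, any count
strictly below `theta × (raw sample total)` is set to zero. Defaults:
`theta = 0.005` for the 16S assay and `0.003` for COI; both are
configuration (`FilterConfig.proportional_thresholds`) and must lie in
(0, 1). Totals are computed on the raw table, before any removal — whether
the denominator should instead exclude non-target reads is genuinely open,
and the raw-total convention is the documented choice here.

**Control filter.** For each taxon, the maximum count across all
extraction negatives, PCR negatives and unused tag combinations defines a
threshold; fecal counts less than or equal to it (inclusive) are zeroed.
Taxa absent from all controls get threshold 0, so the filter is the
identity on positive counts in clean data.

The proportional filter runs first and is not re-applied after the control
filter; the order is a deliberate, documented convention. Filtering is
monotone cell-wise (it never creates reads), and the composition removes a
superset of what either filter removes alone. Control samples themselves
are never modified — they are evidence, not targets. Mock-community
samples pass through the filters (so their recovery can be inspected) but
are excluded from all diet statistics. Repeat assays of one sample are
collapsed by per-cell maximum *before* filtering, preserving any detection
either PCR produced.

**Non-food removal** drops, with per-class tallies: detections outside the
allowed kingdom (default Animalia — environmental DNA such as diatoms,
fungi), the consumer's own DNA (default `Lutra_lutra`), taxa in a
configurable coarse blocklist (e.g. an infraclass-level call covering all
plausible mammal prey and the predator alike), and taxa flagged with a
maximum body size under 3 mm, which are attributed to secondary or
accidental ingestion. A taxon lacking a trait entry is treated as not
small, with a logged warning, so incomplete trait tables degrade loudly
rather than silently.

## Taxonomic reconciliation

The taxonomy is a forest over the seven Linnaean ranks. Sources using
intermediate ranks (infraclass and the like) attach those nodes at the
nearest coarser ladder rank with an `off_ladder` flag; the analyses only
ever compare resolutions at ladder ranks. "Finer" means strictly deeper on
the root path, not a comparison of rank labels across lineages — robust to
ragged trees in which, say, one family has no genus level.

A detection's *scope* is the set of nodes it could denote: one node for an
unambiguous call, several for a composite such as "rudd/roach". Record X
is at least as fine as Y when every node of X lies inside the subtree of
some node of Y. Per sample:

- strictly finer records absorb coarser ones (a genus-level hard-part call
  vanishes when molecular data give two species of the same family);
- equal-resolution records from the two channels merge with provenance
  `both_same_rank`;
- partial overlaps — possible only when composites are involved — collapse
  to the lowest common ancestor of the union, the most specific taxon that
  is certainly correct (marker-to-marker merging never hits this case and
  skips the collapse);
- disjoint lineages coexist: multi-prey samples are real.

Every output record carries a provenance (`only_A`, `only_B`,
`both_same_rank`, `both_diff_rank`), the categories are disjoint, and
their occurrence counts sum exactly to the combined record total — the
basis of the method-comparison statistics. Merging is idempotent and
symmetric up to relabelling of the channel tags.

Before combining with molecular data, morphological records labelled
"insect", "beetle", "mollusk", "snail" or "mammal" are removed (the
default blocklist is configuration): broad invertebrate remains are likely
prey-of-prey, and fur is confounded by the predator grooming itself.

## Covariates

**Scaled mass index.** `SMI_i = M_i · (L0 / L_i)^b` with `L0` the
population mean length and `b` the standardised major axis slope of
log mass on log length, `b = sign(r) · sd(log M) / sd(log L)`. The
exponent should be fitted on the largest available reference population,
not the analysis subset; `build_covariates` accepts reference vectors for
exactly this reason and falls back to the analysis animals.

**Size classes.** Jenks natural breaks (exact Fisher dynamic programme
minimising within-class sum of squares, O(k·n²) with prefix sums) with
k = 3, fitted per sex. Ties among equally good partitions break toward the
lowest feasible cut for reproducibility, and breaks never split tied
values (an optimum with this property always exists). The medium interval
is closed on both ends, so an animal exactly at a boundary is medium.

**River distance.** The mean over candidate rivers' along-network
distances to the coast; animals within 1 km of the coast and closer to it
than to any river get distance zero. The GIS routing itself (river
networks, buffers, land cover, elevation) is out of scope — the package
consumes precomputed per-animal distances and channel lengths.

**Habitat.** Transitional water wins over lake when both are within
2.5 km (half the 10-km-diameter buffer radius; the transitional
designation is the rarer, more specific condition); otherwise main channel
iff `10·main / (10·main + tributary) > 0.5`, strictly — a tie goes to
tributary. The assignment is invariant to rescaling both lengths.

**Season** defaults to meteorological quarters (Dec–Feb winter, and so
on); it is a convention, exposed as such.

## Prey groups and occurrence statistics

A group is present iff any member taxon is present (logical OR), so
grouping never increases a sample's presence count. Taxa too coarse to
assign (defaults: `Salmo_sp`, `Cyprinid`, `Bird`) are dropped with logged
counts; an unknown taxon is an error, not a silent drop. Groups present in
fewer than 3 samples are removed. Frequency of occurrence divides by the
number of samples in the matrix under analysis — i.e. samples with any
dietary data; the denominator is switchable to all screened samples by
passing the unrestricted matrix.

## Multivariate binomial model

Each prey group gets an independent binomial GLM with complementary
log-log link over a shared design matrix: intercept plus treatment-coded
terms, reference level the lexically first, interactions as products of
component columns. Rows with missing modelled covariates are dropped with
a logged count; rank-deficient designs fail with the aliased columns
named.

Fitting is IRLS batched over response columns (`eta` clipped to
[-30, 3.2], fitted probabilities to [1e-10, 1 − 1e-10]); convergence is a
deviance change below 1e-8 within 100 iterations. Constant-response
columns (complete separation of the intercept) are flagged non-converged,
never silently returned. `AIC = deviance + 2·k` per group; the
multivariate AIC is the sum, and stepwise selection makes greedy add/drop
moves on it, never allowing an interaction without its main effects.

The community statistic for a term is the sum over groups of
likelihood-ratio deviances — additive by construction, and monotone under
nesting. Inference is by **parametric bootstrap**: each of B draws
simulates every group from the reduced model's fitted probabilities,
refits full and reduced models, and recomputes the statistic;
`p = (1 + #{D* ≥ D}) / (B + 1)` (add-one convention, so p is never 0 and
never misleadingly fine-grained — B = 999 by default, a warning below
B = 99). The scheme is exact under the binomial model and is the package's
reading of "Monte Carlo resampling" for presence–absence responses.
Per-group p-values are adjusted by Westfall–Young free step-down
resampling over the same simulated statistics, which respects the
correlation among groups; adjusted p-values are monotone in the observed
statistics by construction. The `anova` table adds terms sequentially
(type-I) in the listed order, bootstrapping each test from the model
containing the preceding terms. Bit-for-bit reproducibility: identical
seed and inputs give identical p-values.

## Synthetic data

The generator emulates the study's structure, not any particular dataset:

- ~300 animals with sex-specific lengths (rounded to 5 mm), allometric
  mass with multiplicative noise, uniform longitude/latitude over a
  west–east span, beta-distributed urban fraction, and spatial inputs
  (candidate river distances, coastal flags, channel lengths in buffer);
- true prey groups drawn from the same cloglog model the analysis fits,
  `p = 1 − exp(−exp(alpha_g + beta_lon·lon' + beta_coast·coast'))`, with
  covariates standardised by fixed constants so effects are per ~1 SD
  (a logit option exists for robustness testing). Default effects mirror
  the study's structure: westward salmonids/amphibians/marine prey,
  eastward cyprinids/percids, coastal eel, inland bullhead; intercepts
  target prevalences slightly above the observed frequencies of
  occurrence because detection is imperfect;
- per-marker detection (16S strong on vertebrates, COI on invertebrates),
  resolution ceilings (COI emits "rudd/roach" for either cyprinid,
  family-level calls for some vertebrates), log-normal read depths
  (exp(6.5) ≈ 665 reads median), dominant consumer DNA, Poisson
  contamination (mean 0.10 stray reads per cell) in *all* samples
  including negatives and unused tags, and donor-proportional tag-jump
  counts in unused tag combinations;
- morphology detects each true prey with hard-part probabilities
  (0.25–0.55 by taxon), coarsens through a species→family/genus map, and
  occasionally injects blocklist labels.

Every draw flows from one seed through named, order-independent
substreams, and the truth record labels every stray-read cell, so the
filters' false-positive removal is directly assertable (≥ 95% at the
defaults; measured ≈ 100%).

**What passing tests show — and don't.** Calibration (type-I error within
[0.02, 0.08] at nominal 0.05 over 200 null datasets) and power (≥ 80%
detection of a link-scale unit coast effect through the full pipeline)
hold when the generator and the analysis share the cloglog link and the
true effects are linear in the modelled covariates. Real diets violate
this in ways the generator does not emulate: prey co-occurrence beyond
covariate-driven correlation, overdispersion from repeated local sampling,
reference-database gaps, primer bias correlated with taxonomy, and
contamination that is not independent across cells. The tests validate the
machinery, not the biology.

## Problem sizes used by the checks

The simulation-based checks run at n = 200 with B = 199 over 200
replicates (calibration) and n = 250 with B = 499 over 50 replicates
(recovery); the oracle-equivalence suites use 100 random tables, 500
random 30-node trees, and exhaustive partition search up to n = 12,
k = 4. The acceptance script runs the full pipeline at n = 300 with
B = 499. These sizes are the package's chosen trade-off between
statistical resolution and a test suite that runs in minutes on one CPU.

## Known limitations

- Binary responses only; read counts are never treated as abundance.
- Ordination (latent-variable or NMDS) is out of scope; the group matrix
  and covariates export cleanly to packages that do it.
- The reconciliation rules assume one shared taxonomy; synonym resolution
  and reference-database curation happen upstream.
- The sequential anova depends on term order, as type-I decompositions do;
  put the terms of interest last or use `lr_test` directly for a
  last-entry test.
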