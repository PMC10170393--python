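# otterdiet

Analysis of generalist-predator diets from fecal samples screened with
**multi-marker DNA metabarcoding** and **morphological hard-part
identification**, built around the Eurasian otter (*Lutra lutra*) use case:
hundreds of spraints, a vertebrate-targeted 16S assay, an
invertebrate-leaning COI assay, and sparse microscopy of bones, scales and
exoskeleton.

The package is for ecologists who have per-marker sample × taxon read
tables (with extraction/PCR negatives, unused tag combinations and mock
communities), morphological presence records, and per-animal metadata, and
who want a reproducible route from raw counts to defensible statements
about how diet composition varies over space and between individuals.

## What it does

1. **Filtering** (`otterdiet.filtering`) — per marker, zero any count below
   a proportional threshold of its sample's raw total (0.5% for 16S, 0.3%
   for COI by default; strictly below), then zero any count less than or
   equal to that taxon's maximum across negatives and unused tag
   combinations. Non-food detections (non-animal DNA, the predator itself,
   hopelessly coarse taxa, taxa under 3 mm) are removed with per-class
   tallies.
2. **Reconciliation** (`otterdiet.reconcile`) — merge the markers, and then
   molecular vs morphological channels, per sample: same-lineage detections
   keep the finer call, composites like "rudd/roach" resolve against the
   other channel, genuinely ambiguous overlaps collapse to the lowest
   common ancestor, and every retained presence carries a provenance label
   (one channel / both at the same rank / both at different ranks).
3. **Covariates** (`otterdiet.covariates`) — scaled mass index
   `SMI = M·(L0/L)^b` with `b` the standardised major axis slope of
   log mass on log length; sex-specific size classes by exact Jenks natural
   breaks; river distance to the coast; and a primary-water-habitat
   assignment with 10× weighting of main channels over tributaries.
4. **Diet statistics** (`otterdiet.diet`) — prey-group aggregation (OR over
   member taxa), rarity filtering (< 3 samples), frequency of occurrence,
   per-sample means.
5. **Modelling** (`otterdiet.mglm`) — one binomial GLM with a
   complementary log-log link per prey group over a shared design matrix;
   the community test statistic is the sum over groups of likelihood-ratio
   deviances, with p-values from a parametric bootstrap of the reduced
   model and per-group p-values adjusted by Westfall–Young free step-down
   resampling. AIC-based stepwise term selection operates on the summed
   per-group AIC.
6. **Synthetic data** (`otterdiet.simulate`) — a full generator with known
   truth: spatial diet gradients, marker-specific coverage and resolution
   ceilings, log-normal read depths, Poisson contamination reaching
   negatives and unused tags, tag jumping, and coarse morphology — used by
   the test suite for calibration and recovery checks.

## The model

For sample *i* and prey group *g*, presence `Y[i,g] ~ Bernoulli(p[i,g])`
with

```
log(-log(1 - p[i,g])) = x_i' * beta_g
```

fitted independently per group by IRLS (every column at once, which makes
thousands of bootstrap refits cheap). A term *T* is tested with
`D = sum_g [dev_g(reduced) - dev_g(full)]`; the null distribution of `D`
comes from simulating every group from the reduced fit and refitting both
models, `p = (1 + #{D* >= D}) / (B + 1)`.

## Worked example

```python
import otterdiet as od

result = od.run_all({"seed": 1, "n_otters": 150, "n_resamples": 199})
print(result.outputs["results"].summary())
print(result.outputs["anova"].table.to_string(index=False))
```

prints (abridged):

```
Multivariate binomial GLM (cloglog link)
========================================================================
Samples: 141    Prey groups: 10    Dropped rows: 0
Terms: lon, coast_distance
Community deviance: 1319.9321    Multivariate AIC: 1379.9321
------------------------------------------------------------------------
group                       deviance         AIC   converged
amphibians                  143.0216    149.0216        True
brown_trout                 154.0375    160.0375        True
...
          term  df  deviance  p_value
           lon   1 59.355988    0.005
coast_distance   1 52.116281    0.005
```

141 of 150 simulated otters yielded dietary data after filtering and
reconciliation. Both spatial terms are significant at B = 199 resamples
(the smallest attainable p is 1/(B+1) = 0.005): the generator placed
salmonids, amphibians and marine prey in the west and cyprinids/percids in
the east, and made eel more and bullhead less coastal — and the model
recovers exactly that structure from the noisy, filtered, reconciled
channels.

The same thing from a shell:

```
otterdiet run-all --seed 1 --out runs/demo
otterdiet simulate --seed 1 --n-otters 150 --out data/sim
otterdiet filter --reads data/sim/reads_16s.tsv --marker 16S --out data/f16s.tsv
```

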