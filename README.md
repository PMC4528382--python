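# morphscape

Tools for a recurring question in the biology of colour polymorphism: when
the frequencies of discrete colour morphs vary from population to
population, is that variation explained by **gene flow and genetic
divergence**, or by the **local environment**? The motivating system is a
rock-dwelling agamid lizard with four discrete male throat-colour morphs
(orange, orange-yellow, yellow, grey) sampled across a handful of
semi-arid range sites, with microsatellite genotypes, site coordinates and
environmental covariates (aridity index, topographic relief, vegetation
and rock cover) in hand.

`morphscape` implements the full inference chain as a tested, reusable
library:

* **Morph-frequency statistics** — frequency tables, Pearson χ²
  heterogeneity tests across populations and years, Bonferroni/Holm
  post-hoc pairwise comparisons, Grubbs single-outlier screening.
* **Population-genetic structure** — observed/unbiased expected
  heterozygosity, Monte-Carlo Hardy–Weinberg exact tests, pairwise
  Weir–Cockerham F_ST (θ) with individual-permutation significance and
  Bonferroni flags, and Evanno ΔK post-processing of external clustering
  log-likelihoods.
* **Distance-matrix inference** — the morph-frequency Euclidean distance
  dist(A,B) = √(Σ_m (A_m − B_m)²), great-circle geographic distances,
  |Δx| environmental distances, simple Mantel tests, and **multiple matrix
  regression with randomization (MMRR)**: OLS on vectorized lower
  triangles with slope P values from joint row/column permutation of the
  response matrix, exact (exhaustive n! enumeration) for small designs.
* **AICc multimodel selection** — all predictor subsets (with declared
  collinear-pair exclusions), AICc = n ln(1−R²) + 2k + 2k(k+1)/(n−k−1),
  a ΔAICc ≤ 5 confidence set, renormalized Akaike weights, and relative
  variable importance RIV(v) = Σ weights of retained models containing v.
* **Per-morph environmental regressions** — arcsin√p-transformed morph
  frequencies on log-transformed raw covariates, standardized
  coefficients, Benjamini–Hochberg FDR across the slope-test family, and
  explicit outlier-excluded refits.
* **A synthetic generator** with known ground truth: multinomial-logit
  morph frequencies responding to two covariates, and neutral
  Balding–Nichols microsatellite genotypes whose Dirichlet concentration
  gives direct control of the target F_ST.

The MMRR core follows a statsmodels-style design: build an `MMRR` model
from a response `DistanceMatrix` and named predictor matrices, call
`.fit()`, and get an `MMRRResults` object carrying standardized slopes,
partial correlations, permutation P values, R², AICc and a `summary()`
table.

## Worked example

Generate a synthetic eight-population study and ask whether morph
divergence tracks environment or geography:

```python
from morphscape import *
from morphscape.simulate import SimulationConfig, simulate_dataset

sites, counts, panel, truth = simulate_dataset(SimulationConfig(seed=7))
freqs = frequencies(counts)
md = morph_distance_matrix(freqs)
pool = {
    "distance": geographic_distance_matrix(sites),
    "aridity": covariate_distance_matrix(sites, "aridity"),
    "vegetation": covariate_distance_matrix(sites, "vegetation"),
}
sel = model_selection(md, pool, exclusion_pairs=[("distance", "aridity")],
                      n_permutations=999, seed=7)
print(sel.summary())
print(sel.best_fit.summary())
```

which prints:

```
AICc model selection over predictor subsets
======================================================================
model                                   k      R2   dAICc   weight
aridity+vegetation                      3  0.6832    0.00    1.000
----------------------------------------------------------------------
relative importance of variables (RIV):
  aridity             1.000
  vegetation          1.000
  distance            0.000
======================================================================

Multiple matrix regression (permutation inference)
==========================================================
n pairs: 28    R-squared: 0.6832    AICc: -25.18
permutations: 999
----------------------------------------------------------
predictor         std. slope   r_partial    perm P
aridity               0.4449      0.6199    0.0100
vegetation            0.6806      0.7704    0.0020
==========================================================
```

The environmental matrices carry all the model weight (RIV = 1.0 for
aridity and vegetation, 0.0 for geographic distance), both slopes are
significant under 999 response-relabeling permutations, and the model
explains 68% of the variance in pairwise morph-frequency distance —
exactly the structure the generator planted. The neutral genotypes give a
multilocus Weir–Cockerham θ of 0.0356 against a generator target of 0.04.

A complete dataset (counts CSV, Genepop genotypes, sites CSV, clustering
log-likelihoods, ground truth) plus a ready-to-run config can be written
with the CLI:

```bash
morphscape demo --seed 7 --out demo/
morphscape run --config demo/config.yaml
```

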