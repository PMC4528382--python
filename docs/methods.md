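# Methods

This note documents the statistical procedures implemented in
`morphscape`, the assumptions behind them, the defaults of the synthetic
generator, and the numerical choices made where the design was open.

## The inference problem

Eight-ish populations each carry four discrete male colour morphs. The
observable per population is a multinomial count vector over morphs
(20–48 phenotyped males per site), plus diploid microsatellite genotypes
(~30 individuals × 8 loci), coordinates, and environmental covariates.
The question is whether pairwise divergence in morph frequencies is
predicted by genetic divergence (pairwise F_ST), geography, or
environmental differences — and, at the raw-variable level, which
covariates track each morph's frequency.

## Morph-frequency statistics

Heterogeneity among populations (and between years within a population)
uses the Pearson χ² statistic on the populations × morphs table with no
continuity correction, matching R's `chisq.test` behaviour on r×c tables
(df = (r−1)(c−1); 8 × 4 gives df = 21). Expected counts below 5 raise a
warning rather than silently switching method; an optional Monte-Carlo P
(multinomial resampling under fixed row totals, 10⁴ draws) is available
for sparse tables. A column observed in no population is dropped with a
warning and the df adjusted. Post-hoc pairwise comparisons are 2 × 4 χ²
tests Bonferroni-adjusted by default (Holm available); with 8 populations
there are 28 comparisons.

Outlier screening uses the one-outlier Grubbs test, G = max|x−x̄|/s with
the n−1 sample standard deviation. The P value inverts the
t-distribution critical-value relation; the class of test is explicit:
`two-sided` multiplies the tail by 2n (the textbook two-sided critical
value t_{α/(2n),n−2}), `one-sided` by n, appropriate when a specific
high (or low) extreme is suspected, as when one population shows a
conspicuously high orange frequency. The pipeline uses the one-sided
form for its per-morph screen. Ties on the maximal deviation are broken
to the lowest index and all tied indices reported.

## Population-genetic structure

F_ST uses the Weir–Cockerham (1984) θ estimator: per locus and allele,
the among-population (a), among-individual (b) and within-individual (c)
variance components, combined across alleles and loci by ratio of sums
(Σa / Σ(a+b+c)) — the standard multilocus form, not a mean of per-locus
ratios. Sample sizes enter per locus, so missing genotypes are handled
exactly. Negative estimates are preserved (truncation would distort the
permutation null). Significance for each population pair shuffles whole
individuals (genotypes intact) between the two populations;
P = (#{θ_perm ≥ θ_obs}+1)/(B+1), with a Bonferroni flag at α/n_pairs.
The permutation engine evaluates all relabelings in one set of matrix
products, so 10⁴ permutations over 28 pairs cost seconds.

Heterozygosity per population-locus cell: H_obs is the heterozygote
fraction; H_exp applies the small-sample correction
(2n/(2n−1))(1 − Σp_i²). The Hardy–Weinberg test is a Monte-Carlo exact
test: the observed 2n alleles are re-paired at random, the statistic is
the heterozygote count, and the two-sided P doubles the smaller tail
(each with the +1 correction). This is simpler than a Guo–Thompson chain
and fully reproducible under a seed; it is conservative (measured size
≈0.035 at α = 0.05), which is acceptable for a screening statistic.
Monomorphic cells report P = 1 with a flag.

Cluster-number selection consumes replicate log-likelihoods per K from an
external admixture-clustering program as a plain CSV;
ΔK(K) = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K)), undefined at the
endpoints and wherever the replicate sd is zero (flagged, not infinite).
ΔK is invariant to adding a constant to all log-likelihoods and halves
when all sds double. The hierarchical re-analysis loop is pure
orchestration: a panel is split by externally produced cluster
assignments (per individual or per population) into disjoint, exhaustive
sub-panels; no clustering is performed in-package.

## Distance-matrix inference

The response is the Euclidean distance between four-morph frequency
vectors, bounded by √2. Geographic distance is great-circle (haversine,
km, IUGG mean radius) by default; a planar degrees option exists because
published analyses do not always state their projection. Environmental
distances are |x_A − x_B|.

MMRR regresses the z-scored lower triangle of the response on the
z-scored lower triangles of the predictors (slopes are therefore
standardized; R², t and P are unaffected by the scaling). Because the
n(n−1)/2 pairs are not independent, inference permutes the response
matrix's population labels (rows and columns jointly), refits, and
compares |t| statistics — two-sided by construction and invariant to
predictor scaling. For n ≤ 7 populations the test enumerates all n!
relabelings and the P value is exact; otherwise it samples with the +1
correction so P > 0 always. Partial correlations derive from t:
r_partial = sign(t)·√(t²/(t²+df)). Predictor pairs correlated beyond
1−10⁻¹⁰ raise an error naming the pair. A single-predictor MMRR
degenerates to the simple Mantel test (same |r|, same exact P grid).

Model selection enumerates every non-empty predictor subset that does
not contain a declared exclusion pair (collinear pairs are screened at
|r| ≥ 0.6, closed boundary, on the distance vectors — include the
geographic matrix in the screen to catch spatially structured
covariates). Each model is scored by
AICc = n ln(1−R²) + 2k + 2k(k+1)/(n−k−1) with n the number of pairs and
k the predictor count plus one for the intercept; the additive constant
n ln(TSS/n) is dropped as it cancels in ΔAICc and weights. Models within
ΔAICc ≤ 5 of the best form the confidence set; weights are renormalized
over that set and RIV(v) sums the weights of retained models containing
v. AICc ties within 10⁻⁹ resolve to the smallest predictor set. The
treatment of the 28 pairwise distances as n independent observations
follows standard practice for this method; it is a known
pseudo-replication caveat of distance-matrix model selection and is
deliberately not "corrected" here — see Limitations.

## Per-morph environmental regressions

To interpret distance-level results on the raw variables, each morph's
frequency is arcsine-square-root transformed (the angular transform for
proportions) and regressed on log-transformed covariates (natural log;
zero values get a documented ε = 10⁻⁶ shift with a warning, negative
values are an error). Predictors are z-scored after the log — the choice
is immaterial to the reported standardized coefficients
(slope·sd(x)/sd(y)), which are invariant to affine predictor rescaling.
The FDR family is all slope P values across the four morph fits
(Benjamini–Hochberg). Outlier exclusion is only ever by an explicitly
named population (fed by the Grubbs screen), never automatic.

## The synthetic generator

The generator emulates the study design, not any particular dataset:

* **Sites** — n sites with coordinates in a semi-arid ranges footprint;
  an aridity index (precipitation/potential evaporation; mean 0.20, sd
  0.05, floored at 0.02) constructed to correlate with longitude at
  ρ = 0.64 by default (the magnitude reported for the
  distance–aridity confound in this kind of landscape); vegetation and
  rock proportions from logistic-normal draws; log-normal topographic
  relief.
* **Morph counts** — per population,
  η = intercepts + B·z(covariates) + N(0, σ) on the log-odds scale and
  p = softmax(η); counts are multinomial over the phenotyped males
  (defaults 22, 48, 29, 22, 26, 20, 21, 20 — the field sample sizes).
  The default effect matrix B couples orange (−0.89) and yellow (+0.86)
  to the aridity index and orange-yellow (+0.83) and grey (−0.74) to
  vegetation, magnitudes taken from the standardized coefficients
  reported for this system; a negative aridity-index slope means "more
  of that morph where drier". The logit noise σ = 0.25 puts the
  realized per-morph regression R² at about 0.75–0.84, inside the
  0.45–0.85 band such field regressions occupy. Noise on the logit
  scale (not the counts) makes overdispersion relative to multinomial
  sampling controllable.
* **Genotypes** — Balding–Nichols: per locus, ancestral frequencies are
  Dirichlet over 4–12 alleles; population frequencies are Dirichlet with
  concentration p(1−F)/F, so the expected Weir–Cockerham θ equals the
  target F (the F → 0 limit copies ancestral frequencies exactly).
  Genotypes are drawn in Hardy–Weinberg proportions; missingness is an
  explicit zero code at a configurable rate (default 0). This
  parameterization is chosen precisely because it gives direct F_ST
  control; no migration/drift forward simulation and no
  frequency-dependent selection are modelled, so the generator validates
  the estimators and the inference chain, not demographic realism.
* **Clustering likelihoods** — a synthetic stand-in for external
  admixture-program output: mean ln P(X|K) rises to the true K then
  plateaus with mild decline, Gaussian replicate scatter. It emulates
  the shape only.

Everything is reproducible bit-for-bit from a single seed; independent
streams per artifact mean sites, counts and genotypes can be regenerated
in isolation.

What passing tests on this generator do **not** show: robustness to null
alleles, linkage between loci, temporally varying morph frequencies,
non-equilibrium demography, or measurement error in the covariates —
none of which the generator produces.

## Calibration and recovery results (computed, not asserted from memory)

The studies in `morphscape.calibration` (also run by
`scripts/acceptance.py`) measure, at the defaults above:

* MMRR slope permutation tests under a null generator hold their nominal
  α = 0.05 within Monte-Carlo error (999 permutations, 1000 replicates).
* The Monte-Carlo HWE test is conservative (size < 0.05).
* Mean multilocus θ over 200 replicate panels matches the generator
  target within ±0.015 at F = 0.05.
* With environmental effects on, the orange-vs-aridity standardized
  coefficient recovers the generated sign in essentially every
  replicate; both environmental RIVs exceed RIV(F_ST) in most but not
  all replicates (≈85%, see Limitations).

## Numerical choices

* Permutation P values use the +1 correction except under exhaustive
  enumeration, where they are exact fractions of n!.
* Comparisons against observed statistics use a 10⁻¹² slack so ties
  count as exceedances on either route.
* Zero-variance responses/predictors, R² = 1 in AICc, n ≤ k+1 designs,
  and zero-sd ΔK denominators are explicit errors or flagged-undefined
  values, never silent infinities.
* Perfect fits (zero residual) report infinite t as |r_partial| = 1 with
  the P value still defined by the permutation distribution.

## Limitations

* **RIV has a heavy null tail at this design size.** With 8 populations
  the 28 pairwise distances carry roughly 8 independent pieces of
  information, but AICc uses n = 28; in pure-noise simulations some
  variable attains RIV > 0.9 in ~20–30% of replicates, and in
  signal-on simulations the environmental RIVs outrank the (truly
  neutral) F_ST RIV in about 85% of replicates rather than always.
  RIV rankings from a single dataset of this size should be read as
  descriptive support measures, not calibrated tests — the permutation
  P values, which are correctly calibrated, carry the inferential
  weight.
* The arcsine-OLS regressions are kept for fidelity to standard practice
  in this literature; a multinomial/beta GLM would be the modern choice
  but is deliberately out of scope.
* Admixture clustering itself (MCMC) is external; only the ΔK
  post-processing and the hierarchical splitting logic are implemented.
* Null-allele detection and linkage-disequilibrium QC are out of scope.
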