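# Methods

This note documents the models, the numerical choices, and what the
synthetic tests do and do not demonstrate.

## Clustering and GVF

Samples are clustered per water type on their raw (δ¹⁵N, δ¹⁸O) values —
both tracers share the ‰ scale, so no standardization is applied by default
(an option exists). Ward's minimum-variance criterion with squared
Euclidean distance is used: each step merges the pair of clusters whose
union minimally increases the total within-cluster sum of squares. Merge
costs are reported as that ΔSS itself. The linkage is computed via
scipy's hierarchical clustering (heights h converted to ΔSS = h²/2) and is
validated in the test suite against an independent first-principles O(n³)
agglomeration on randomly generated instances. Determinism follows from the
deterministic nearest-neighbor-chain algorithm; exact-tie ordering follows
scipy's convention. Flat cuts undo the last k−1 merges and label clusters
1..k by order of first member appearance.

Partition quality is the goodness of variance fit, GVF = 1 − SDCM/SDAM,
with SDAM/SDCM pooled across tracers by summation (consistent with the
squared Euclidean geometry). GVF is 0 for the single-cluster partition, 1
for all-singletons, and non-decreasing along nested cuts. Degenerate case:
if all samples are identical (SDAM = 0), GVF is defined as 1 with a logged
notice. GVF is defined at the partition level; per-group reporting is
common in field studies but its construction is usually left implicit. This
package's per-group variant is 1 − (within-group SS about the group mean) /
(SS of the group's members about the grand mean of all samples of the same
water type), with a size-1 group defined as 1. This is explicitly this
package's interpretation, not a standard statistic.

## Mixing model

The model treats each observed tracer value as a proportion-weighted
mixture of endmember signatures with fresh source and fractionation
realizations per observation plus residual error. Marginalizing the latent
normals gives a closed-form likelihood:

    X_ij ~ N( Σ_k P_k (μ_jk + λ_jk),  Σ_k P_k² (ω_jk² + τ_jk²) + σ_j² ).

Independent per-observation source realizations are an assumption — the
alternative (one shared realization for all observations) produces a
different, correlated covariance; the independent form is standard in
mixing-model practice and is cross-checked in the tests against numerical
quadrature of the unmarginalized model. Note the P² weighting: mixtures
concentrated on one source inherit that source's full variance, while
balanced mixtures average variance away. This term matters — it is what
lets data distinguish points along the direction in which the mixture
*mean* is uninformative (see "Identifiability" below).

Fractionation defaults to λ = τ = 0 for every source: nitrate mixing
studies conventionally treat transport as conservative, and no defensible
nonzero values ship with the package. Nonzero tables are accepted via the
`frac_mean`/`frac_sd` columns.

Priors: Dirichlet(1,…,1) on P (uniform over the simplex) and independent
half-normal(s₀ = 20 ‰) on each σ_j — weakly informative on the ‰ scale of
nitrate isotopes, configurable via `sigma_prior_scale`.

### Sampler

Inference runs on unconstrained coordinates: additive-log-ratio (softmax)
coordinates z ∈ R^(K−1) for P and log σ, with the corresponding Jacobian
terms (Σ_k log P_k and Σ_j log σ_j) added to the target. Each of the
`n_chains` chains is an independent seeded Metropolis sampler; per
iteration it performs one component-wise sweep (one adaptive scale per
coordinate, tuned toward ~44 % acceptance) plus one joint move drawn from
the empirical covariance of the burn-in history scaled by 2.38/√d. The
joint move exists because the posterior concentrates on a ridge when K
sources are seen through fewer than K−1 tracers; axis-aligned proposals
alone mix poorly along it (observed split-R̂ ≈ 1.5), while the
covariance-informed move restores R̂ ≤ 1.05 at moderate chain lengths.
All adaptation is confined to burn-in, so the post-burn-in kernel is a
fixed Metropolis kernel satisfying detailed balance.

Defaults are 3 chains × 50,000 iterations (25,000 burn-in, thin 10);
the tests and the acceptance script use 2–3 chains × 4,000–30,000, which
the convergence diagnostics support for these problem sizes. Chains are
seeded from `SeedSequence(rng_seed, spawn_key=(chain,))`, making every fit
bit-reproducible. Convergence is summarized by plain split-R̂ per reported
parameter; if any R̂ exceeds the threshold (default 1.05) the fit returns
its draws but withholds the summary table, with a logged warning.

Degenerate cases: K = 1 returns P = 1 in every draw; zero total variance
with data off the mean yields −∞ log-likelihood (a valid log-density);
summary tables order sources CF, MS, NP, SN when those ids are present.

## Diagnostics

* **Nitrification window**: nitrate produced by nitrification takes one
  oxygen in three from dissolved O₂ (δ¹⁸O ≈ +23.5 ‰, configurable) and two
  from ambient water, so its δ¹⁸O lies between
  (1/3)·δ¹⁸O–O₂ + (2/3)·δ¹⁸O–H₂O evaluated at the observed water minimum
  and maximum. Classification against the window uses the closed interval;
  missing δ¹⁸O values are "not evaluable", never silently excluded.
* **Correlation screens**: Pearson r with the two-tailed t-test on n−2
  degrees of freedom, pairwise deletion of missing values, α = 0.01 by
  default (0.05 is the documented alternative). The mapping from
  (pair, sign, significance) to an interpretation is a declarative rule
  table: significant negative δ¹⁵N–ln(NO₃⁻) (Rayleigh behavior) or
  significant positive δ¹⁵N–δ¹⁸O ⇒ denitrification signal; significant
  negative δ¹⁵N–δ¹⁸O ⇒ mixing with no heavy-isotope enrichment; otherwise
  not significant. The table codifies narrative reasoning common in
  isotope biogeochemistry and is overridable. Non-positive NO₃⁻ values are
  dropped pairwise from the log pair with a logged notice.
* **Exceedance flags**: strict inequalities against the WHO drinking-water
  nitrate guideline (50 mg/L) and a configurable total-nitrogen threshold
  (shipped default 2.0 mg/L, an external-standard constant exposed in
  config rather than hard-coded). Missing concentrations give
  "not evaluable" flags.

Concentrations are stored exactly as given (mg/L of the stated species);
no nitrogen-equivalent conversion is applied, because source tables in this
field report both conventions without always saying which.

## Synthetic data and the basin scenario

The generator draws, per sample, fresh source and fractionation
realizations, mixes them with the group's true proportions, and adds
residual noise; NO₃⁻ concentrations are lognormal per group (so ln NO₃⁻ is
always defined); conductivity loosely tracks the nitrate load; ambient
water δ¹⁸O is uniform over a configurable range. An optional Rayleigh
overprint multiplies NO₃⁻ by a fraction remaining f ~ U(f_range) and shifts
δ¹⁵N by ε·ln f and δ¹⁸O by (ε/2)·ln f (the 2:1 N:O enrichment convention;
the ratio is configurable).

The packaged basin scenario has 29 surface + 33 ground samples in four
groups whose true proportions follow the qualitative pattern of a
hilly-basin field study: a soil-N/fertilizer surface group (SN 0.48,
CF 0.32), a fertilizer/manure-sewage surface group (CF 0.48, MS 0.33), a
mixed ground group (MS 0.34, CF 0.31, SN 0.29) and a manure/sewage-dominated
ground group (MS 0.80), the last with a mild denitrification overprint
(ε = −5 ‰, f ∈ (0.6, 1)) kept weak deliberately so the isotopic shift does
not bias that group's mixing fit; a separate high-power scenario
(ε = −8 ‰, f ∈ (0.2, 1)) exercises the denitrification detector.

### Identifiability of the packaged geometry

With two tracers and four sources the mean map P ↦ Σ P_k μ_k has a
one-dimensional null space: an entire segment of the simplex produces the
same mixture mean, and the posterior mean lands near the segment's center
rather than at the truth unless the geometry cooperates. The packaged
signatures are therefore designed, not arbitrary:

* SN sits at the weighted centroid 0.6·CF + 0.2·MS + 0.2·NP, which aligns
  the null direction with an "SN versus weighted mix" trade whose feasible
  range is roughly centered on each scenario truth;
* NP carries a wide δ¹⁸O SD (7 ‰), so positions along the residual ridge
  disagree in the P²-weighted mixture variance and the likelihood's
  variance term localizes the posterior.

The qualitative arrangement matches how these endmembers sit in real
dual-isotope compilations (NP high δ¹⁸O, MS high δ¹⁵N, CF low in both, SN
intermediate δ¹⁵N with low δ¹⁸O), but the numbers are synthetic. Passing
recovery tests on this scenario therefore shows that the estimator is
correct and well calibrated *under favorable, known geometry*; it does not
show that any field dataset's sources are identifiable. With overlapping
real-world signatures the posterior will honestly widen, and contributions
along the degenerate direction will shrink toward the prior.

What the generator does not emulate: spatial correlation between nearby
samples, seasonal dynamics, concentration-dependence of mixing
(concentration-weighted models are out of scope), correlated source
signatures, or measurement-error structure beyond i.i.d. normals.

A packaged CSV (`data/basin_group_stats.csv`) carries per-region
hydrochemical means ± SD for seven region groups of a real hilly-basin
survey, for moment-matched synthesis and smoke tests; the "±" values are
treated as SDs.

## Numerical choices and edge cases

* Tracer order is fixed by `AnalysisConfig.tracers` and used identically
  for clustering features and likelihood dimensions, preventing silent
  permutation bugs.
* CSV dialect: comma-separated, UTF-8, mandatory header, "." decimal,
  empty string = missing; read ∘ write is the identity on the schema.
* Simplex draws are validated to |ΣP − 1| ≤ 1e−12 componentwise ≥ 0 on
  every fit.
* Pearson screens treat exactly-constant inputs as not evaluable rather
  than emitting NaN.
* k = 2 clusters per water type is the default (exposed in config);
  automatic k selection is out of scope beyond reporting GVF across k.

## Problem sizes used in tests

The suite fits reduced chains (2–3 × 4,000–30,000 iterations) on groups of
13–60 samples; the grid-oracle comparison uses a 1,200 × 400 grid over
(P₁, σ) for a 25-sample, one-tracer problem; the Ward oracle comparison
runs 100 random instances with n ≤ 25; the null false-positive simulation
uses 200 replicates of 50 samples. These sizes give Monte-Carlo error well
inside the asserted tolerances while keeping the suite fast.

## Known limitations

* Random-walk Metropolis scales poorly beyond a handful of sources and
  tracers; K ≫ 5 would warrant gradient-based samplers.
* Summary tables report the posterior SD of P_k, which is not the same as
  the across-sample SD of per-sample contributions (per-sample
  contributions are not modelled; the model is a single mixture per group).
* The per-group GVF construction is interpretive (see above).
* No hierarchy is shared across groups: each cluster's proportions are fit
  independently, matching per-group application of mixing models in field
  practice but forgoing partial pooling.
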