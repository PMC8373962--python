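# nitratrace

Nitrate (NO₃⁻) pollution in mixed-use river basins rarely has a single
origin: chemical fertilizer (CF), manure and sewage (MS), atmospheric
precipitation (NP) and soil nitrogen (SN) all leave overlapping fingerprints
in the water. The dual stable isotopes of dissolved nitrate —
δ¹⁵N–NO₃⁻ (‰ vs air-N₂) and δ¹⁸O–NO₃⁻ (‰ vs VSMOW) — separate these
endmembers well enough that a Bayesian mixing model can quantify each
source's contribution, provided samples are first grouped into
hydrochemically coherent clusters.

`nitratrace` packages that workflow for hydrochemists and water-quality
analysts:

1. **Ward clustering** of samples per water type (surface/ground) on their
   raw isotope values with squared Euclidean distance, scored by the
   goodness of variance fit, GVF = 1 − SDCM/SDAM (SDAM: total squared
   deviation about the grand mean; SDCM: the same about class means).
2. **Bayesian isotope mixing model** per cluster. Each observation is
   modelled as

   X_ij = Σₖ Pₖ (S_jk + C_jk) + ε_jk,  S_jk ~ N(μ_jk, ω_jk²),
   C_jk ~ N(λ_jk, τ_jk²),  ε_jk ~ N(0, σ_j²),

   with the proportions P on the simplex under a Dirichlet(1,…,1) prior and
   half-normal priors on the residual scales σ_j. The marginal likelihood is
   normal with mean Σₖ Pₖ(μ_jk + λ_jk) and variance
   Σₖ Pₖ²(ω_jk² + τ_jk²) + σ_j². Sampling is seeded random-walk Metropolis
   on softmax/log coordinates with burn-in-only adaptation; convergence is
   checked with split-R̂.
3. **Biogeochemical diagnostics**: the theoretical nitrification δ¹⁸O window
   ((1/3)·δ¹⁸O–O₂ + (2/3)·δ¹⁸O–H₂O evaluated at the ambient-water
   extremes), Pearson correlation screens for denitrification
   (δ¹⁵N vs ln NO₃⁻, δ¹⁸O vs δ¹⁵N, conductivity vs NO₃⁻) with a
   configurable interpretation rule table, and WHO / surface-water-standard
   exceedance flags.
4. **Synthetic data** with known ground truth (group-wise mixing
   proportions, optional Rayleigh denitrification overprint), so the whole
   pipeline is testable without field data.

Clustering and the mixing model are scikit-learn-style estimators
(`WardClusterer`, `BayesianMixingModel`) and compose with sklearn
tooling; module-level functions (`ward_linkage`, `fit_mixing_model`, …)
are thin wrappers.

## Worked example

Generate the packaged basin scenario (29 surface + 33 ground samples, four
latent groups with known proportions) and run the full pipeline:

```bash
nitratrace simulate --scenario basin-demo --seed 1 --out demo/data
nitratrace run-all --samples demo/data/samples.csv \
                   --sources demo/data/sources.csv --out demo/run --seed 1
```

`demo/run/contributions.csv` (mean ± SD of each source's contribution, %):

```
group,source,mean_pct,sd_pct
ground-1,CF,28.6,8.3
ground-1,MS,32.5,2.9
ground-1,NP,5.5,2.8
ground-1,SN,33.4,13.7
ground-2,CF,3.5,2.1
ground-2,MS,84.2,1.8
ground-2,NP,6.6,1.7
ground-2,SN,5.8,3.6
surface-1,CF,35.0,11.1
surface-1,MS,10.2,3.8
surface-1,NP,10.7,3.8
surface-1,SN,44.1,18.3
surface-2,CF,47.6,5.9
surface-2,MS,31.0,2.5
surface-2,NP,3.0,1.9
surface-2,SN,18.4,9.7
```

Each row is a posterior summary of one source's share in one cluster. The
scenario's generating truths are recovered: the soil-N/fertilizer-dominated
surface group (true SN 48 %, CF 32 %) comes back as 44.1/35.0; the
manure-and-sewage-dominated ground group (true MS 80 %) comes back as
84.2 %. `gvf.csv` reports the clustering quality:

```
scope,label,gvf
surface,partition,0.7426161632425228
surface,1,0.8107123346648462
surface,2,0.6730381204582407
ground,partition,0.9479422458210292
ground,1,0.9774568698689503
ground,2,0.9184752376759283
```

A GVF above ~0.7 indicates the two-group split explains most of the isotope
variance. The run directory also contains per-sample cluster assignments,
posterior draws per group, correlation screens per region and cluster,
nitrification-window classifications, exceedance flags, and a manifest with
seeds, R̂ values and file digests.

For your own data, supply `samples.csv` (columns `sample_id, water_type,
region, d15N_NO3, d18O_NO3, no3, tn, nh4, cond, d18O_H2O`) and
`sources.csv` (long form `source_id, tracer, mean, sd[, frac_mean,
frac_sd]` or the wide equivalent). The packaged source signatures are
synthetic/illustrative; real analyses must provide measured or literature
endmember values.

## Layout

```
src/nitratrace/
  datatypes.py   sample/source/config types
  io.py          CSV readers/writers, validation
  cluster.py     Ward linkage, tree cutting, GVF, WardClusterer
  mixing.py      likelihood/prior, Metropolis sampler, BayesianMixingModel
  diagnostics.py nitrification window, correlation screens, exceedance flags
  synthetic.py   ground-truth generators and the packaged basin scenario
  pipeline.py    cluster -> mix -> diagnose orchestration
  cli.py         simulate / cluster / mix / diagnose / run-all
docs/methods.md  model assumptions, parameter choices, limitations
```
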