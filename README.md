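# georisk

Design-based incidence estimation and model-based geostatistical risk
mapping for stratified two-stage cluster surveys, with a synthetic-data
generator that emulates a national community survey (9 strata, ~125
clusters per stratum, ~150 persons per cluster).

The pipeline has six stages:

1. **simulate** — country-like covariate surfaces (elevation, population
   density, agricultural-worker share, climate zones) on a planar-km
   grid, stratified cluster samples, a latent Gaussian field with
   exponential covariance, and Poisson outcome counts.
2. **survey** — design-based rate estimation: per-stratum ratio
   estimates with linearized (with-replacement PSU) variances,
   population-weighted national rates, and extrapolated event counts.
3. **explore** — Poisson GLMs with an exposure offset, piecewise-linear
   (hinge) covariate effects with a deviance-profile breakpoint scan,
   Pearson residuals and the empirical semivariogram.
4. **fit** — the geostatistical Poisson log-linear model
   `Y_i ~ Poisson(n_i * exp(beta'd_i + S_i + Z_i))` with exponential
   (Matern 1/2) spatial covariance and a nugget, fitted by Monte Carlo
   maximum likelihood: a preconditioned Langevin (MALA) sampler for the
   latent field, importance-sampling likelihood-ratio maximisation with
   analytic gradients, and anchor re-location until convergence.
5. **predict** — plug-in conditional simulation (kriging) of the
   spatially structured incidence surface at grid locations.
6. **map** — exceedance probabilities per incidence threshold and
   hot (p >= 0.7) / cold (p <= 0.3) / intermediate classification.

A set of published reference summary tables (province-level counts and
rates, sex-specific rates, clinical features) is embedded under
`georisk.datasets` and used for worked-example cross-checks.

## CLI

```sh
georisk run --config config.yaml --seed 7 --outdir out/
georisk survey --config config.yaml     # run only up to the survey stage
```

Configuration is YAML or JSON and validated before any stage runs; see
`georisk.config.PipelineConfig` for all fields and defaults.  Every
stage writes its artifacts (CSV/JSON) into the output directory along
with a `manifest.json` recording the seed, config hash, package version
and per-stage wall times.  Runs are byte-reproducible for a fixed seed.

Minimal config:

```yaml
seed: 7
outdir: out
simulate:
  extent_km: [120, 120]
  resolution_km: 5
  clusters_per_stratum: 25
thresholds: [300, 398, 500]
```

To analyse real data instead of simulating, set
`simulate: {enabled: false}` and point `clusters_path` / `strata_path`
(and optionally `grid_path`) at CSV files; cluster tables may carry
planar `x_km`/`y_km` coordinates or `lon`/`lat` degrees, which are
projected equirectangularly at the mid-latitude.

## Layout

```
src/georisk/
  synthetic.py    # domain, cluster sampling, field + count simulation
  survey.py       # ratio estimators, national rates, extrapolation
  covariates.py   # model specs, hinge terms, GLM, breakpoint scan
  geostat.py      # covariance, MALA sampler, MCML, variogram
  mapping.py      # kriging, incidence surfaces, exceedance maps
  io.py           # validated CSV readers/writers, projection
  datasets.py     # embedded reference summary tables
  config.py, pipeline.py, cli.py
```
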