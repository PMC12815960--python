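# ppmr

Stomach-content analysis of predator–prey mass ratios (PPMR) across
temperature and commercial-fishing gradients in marine food webs.

Diet surveys such as Cefas' DAPSTOM database record, for each sampled
predator, the prey found in its stomach with their counts and individual
wet weights. For one stomach the biomass-weighted predator–prey mass ratio
is

```
PPMR = M_pred / ( (1/n) Σ_j M_j )
```

where the denominator is the abundance-weighted arithmetic mean prey mass
(each of the `n` prey individuals counted once). PPMR constrains trophic
interaction strength and energy flux through size-structured food webs;
how it varies with sea-surface temperature (SST) and fishing pressure is
the question this package operationalises via a space-for-time
substitution:

* **spatiotemporal matching** — each stomach is joined to the monthly mean
  SST of its grid cell for the *previous* calendar month (a one-month lag),
  and to annual commercial fishing hours for its ICES statistical rectangle
  (0.5° latitude × 1° longitude, codes like `31F4`);
* **hierarchical models** — `log10 PPMR` (and log10 predator mass, mean
  individual prey mass, prey count, prey richness) are fit against
  temperature, standardized log10 effort, and their interaction, with
  crossed random intercepts for rectangle, season and predator species
  (REML; AIC-based linear-vs-quadratic comparison);
* **size structure** — small/medium/large prey classes, effort terciles for
  stratified trend lines, and a species-level classification of body-size
  responses (increase / decrease / no change, as percent of species and of
  biomass);
* **ordination** — family × rectangle abundance matrices, Bray–Curtis nMDS,
  and environmental vector fitting with permutation tests;
* **synthetic data** — a generator that emulates all three input tables
  under a known true model, so every stage is covered by parameter-recovery
  tests. Calibrated presets (`paper_ppmr`, `paper_interaction`,
  `paper_preymass`, `paper_predmass`) encode published effect sizes such as
  a log10-PPMR temperature slope of 0.041/°C and conditional slopes of
  0.03 (low fishing) vs 0.10 (high fishing).

## Worked example

Simulate the interaction preset (5,000 stomachs), match covariates, compute
per-stomach PPMR, and fit the temperature × effort mixed model:

```python
import dataclasses
from ppmr import synthetic_data, dapstom_io, glmm_pipeline, size_structure, ppmr_core

cfg = dataclasses.replace(synthetic_data.preset("paper_interaction"),
                          n_stomachs=5000, seed=1)
ds = synthetic_data.generate(cfg)
matched = dapstom_io.build_matched_table(
    ds.stomachs, dapstom_io.EnvLayer(ds.sst), dapstom_io.EffortTable(ds.effort))
tab = glmm_pipeline.build_analysis_table(matched)
fit = glmm_pipeline.fit_model(glmm_pipeline.ModelSpec(with_effort=True), tab)
bins = size_structure.effort_terciles(tab["effort_hours"])
print(glmm_pipeline.stratified_trendlines(fit, bins))
```

prints (seed 1):

```
temperature slope: 0.0667 (SE 0.0026)
interaction:       0.0369 (SE 0.0012)
stratum  median_effort_hours  intercept    slope
    low               415.09   2.219529 0.030156
 medium               687.38   1.956183 0.067561
   high              1063.46   1.728337 0.099924
```

The conditional temperature slope of log10 PPMR at the median of each
effort tercile recovers the generating values (0.03 low, 0.10 high): in
heavily fished areas the predator-to-prey size ratio rises much faster with
temperature. Back-transformed, a slope of 0.030 is a
`(10**0.030 - 1)*100 = 7.2%` increase in PPMR per °C
(`ppmr_core.pct_change_per_degree`), compounding across the full
temperature span via `pct_change_over_gradient`.

The same steps are available as a CLI:

```sh
ppmr simulate --preset paper_interaction --n 5000 --seed 1 --out-dir run/
ppmr match --stomachs run/stomachs.csv --sst run/sst.csv --effort run/effort.csv --out run/matched.csv
ppmr compute --in run/matched.csv --out run/ppmr.csv
ppmr fit --data run/ppmr.csv --response log10_ppmr --with-fishing --out run/fit.json
ppmr run --config run.yaml     # full pipeline with a manifest
```

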