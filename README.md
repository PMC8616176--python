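# clonefit

Quantitative analysis of drug-sensitive versus drug-resistant tumour cell
clones, built for studies of acquired multidrug resistance (for example
efflux-transporter-driven resistance in high-grade serous ovarian cancer,
where resistant clones pay a proliferative cost for pump expression and are
outcompeted by sensitive clones off treatment). The package covers five
stages that such studies chain together, each usable on its own:

* **growth** — logistic fits of confluence / fluorescence-area time series.
  Each clone's trajectory is summarised by
  `x(t) = K / (1 + ((K − x0)/x0) e^{−rt})`; the intrinsic growth rate `r`
  (1/h) is the clone's absolute fitness, with doubling time `ln 2 / r` and
  analytic time-to-threshold. Clone groups are compared by a pooled-variance
  Student t-test on fitted rates.
* **competition** — the two-clone Lotka–Volterra model

  ```
  dx_s/dt = r_s x_s (1 − (x_s + α_sr x_r)/K_s)
  dx_r/dt = r_r x_r (1 − (x_r + α_rs x_s)/K_r)
  ```

  fitted to mono- and co-culture curves across seeding ratios; the
  coefficient ratio `α_rs/α_sr` measures how asymmetrically the sensitive
  clone crowds out the resistant one, with uncertainty from a
  residual-resampling bootstrap.
* **dose_response** — four-parameter-logistic viability fits with absolute
  IC50 (dose at 50% of vehicle control), fold-resistance between clone
  groups, the growth-rate-corrected metric
  `GR(c) = 2^{log2(x_c/x0)/log2(x_ctrl/x0)} − 1` with GR50 (UTBD-flagged
  when the curve is flat or never crosses 0.5), and independent-action
  mixture IC50 predictions for sensitive/resistant co-cultures.
* **screen** — 384-well screen normalization (fold change to the per-plate
  negative-control median), robust Z-scoring against the dataset, primary
  hit calling (<50% of control at ≥1 dose in *every* cell line) and
  validation nomination (robust Z < −2 at ≥2 dose points).
* **morphology** — per-cell feature tables robust-Z-scored to a reference
  population, iterative variance/correlation feature reduction (|Pearson r|
  cut 0.85), and per-feature Welch tests with Benjamini–Hochberg correction.

A first-class `datasets` module generates every input with a ground-truth
sidecar (logistic curves, LV co-cultures, plate tables with batch factors and
planted hits, 4PL viability tables, morphology tables with correlated blocks
and inactive features), so the whole pipeline is testable end to end with
known answers.

The main fitting operations are scikit-learn-style estimators
(`LogisticGrowthModel`, `LotkaVolterraCompetition`, `FourPLModel`,
`GRCurveModel`, `ReferenceRobustScaler`, `CorrelationFeatureReducer`) with
`fit`/`predict`/`transform`, `get_params`, and trailing-underscore fitted
attributes; module-level functions are thin wrappers.

## Worked example

Fit the shipped study scenario — five sensitive clones doubling every 22 h,
five resistant clones doubling every 44 h, then a co-culture competition
experiment at 25:75 / 50:50 / 75:25 seeding with 5% measurement noise:

```python
import numpy as np
from clonefit import datasets, fit_curves, compare_fitness, fit_lv

presets = (datasets.make_clone_panel(datasets.FUSION_NEGATIVE, 5)
           + datasets.make_clone_panel(datasets.FUSION_POSITIVE, 5))
curves, _ = datasets.make_growth_curves(presets, seed=11)
fits = fit_curves(curves)                      # one logistic fit per replicate
per_clone = fits.groupby("clone")["r"].mean()
neg = [v for c, v in per_clone.items() if "negative" in c]
pos = [v for c, v in per_clone.items() if "positive" in c]
res = compare_fitness(neg, pos)

co, _ = datasets.make_coculture(seed=7)
model = fit_lv(co)
model.bootstrap(n_boot=200, seed=7)
```

which prints:

```
mean r sensitive  = 0.03140 /h  (t_d = 22.1 h)
mean r resistant  = 0.01578 /h  (t_d = 43.9 h)
fitness ratio     = 1.99   (t = 36.4, df = 8, p = 3.56e-10)
alpha_sr = 0.185, alpha_rs = 0.695
competitive asymmetry alpha_rs/alpha_sr = 3.75  [95% bootstrap CI 3.17-4.86]
```

The logistic fits recover the 2-fold fitness advantage of the sensitive
group (truth: `r` ratio 2.0), and the LV fit recovers the 3.5-fold
competitive asymmetry planted in the generator (`α_sr = 0.2`,
`α_rs = 0.7`) to within the sampling error of a 4-replicate experiment.

The same stages are scriptable from a shell:

```sh
clonefit simulate coculture --seed 7 -o out/
clonefit compete fit out/coculture.csv --n-boot 200 --seed 7 -o out/
clonefit simulate screen --seed 1 -o out/
clonefit screen call-hits --plates out/plates.csv -o out/
```

Every output directory contains a `provenance.json` (config, seed, package
version) sufficient to regenerate it.

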