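# Methods

This note documents the models implemented in `clonefit`, the synthetic data
they are validated against, the defaults and why they were chosen, and the
numerical and design decisions a user should know before trusting the
output on their own data.

## Logistic growth and fitness

Single-clone trajectories (confluence %, or fluorescence area per image in a
labelled co-culture channel) are modelled as logistic growth

    x(t) = K / (1 + ((K − x0)/x0) · e^{−r t}),

with intrinsic growth rate `r` (1/h), carrying capacity `K` (signal units)
and inoculum `x0`. `r` is the low-density exponential rate and serves as an
absolute fitness measure; doubling time is `ln 2 / r`, and the time to any
signal threshold has the closed form
`t = ln(((K − x0)/x0) / ((K − th)/th)) / r`, which the package uses instead
of interpolating noisy raw curves (raw interpolation is available as a flag).

Fitting is bounded nonlinear least squares on the raw signal scale
(`scipy.optimize.curve_fit`, bounds `r ∈ (0, 1]`/h,
`K ∈ (max/2, 10·max]`, `x0 ∈ (0, 3·first value]`), initialised from the
slope of `log(x/(K − x))` over the first half of the series. On noiseless
logistic data the parameters are recovered to machine precision for
`r ∈ [0.005, 0.1]`/h. Each replicate is fitted independently and clones are
summarised by replicate means, so per-clone dispersion is visible rather
than averaged away before fitting.

Groups of clones are compared with a pooled-variance two-sample Student
t-test on per-clone mean rates (`df = n_A + n_B − 2`; two groups of five
give the integer `df = 8` that a Welch test would not), and the ratio of
group-mean rates is reported as the relative fitness.

## Two-clone Lotka–Volterra competition

Co-cultures of a sensitive clone `s` and a resistant clone `r` follow

    dx_s/dt = r_s x_s (1 − (x_s + α_sr x_r)/K_s)
    dx_r/dt = r_r x_r (1 − (x_r + α_rs x_s)/K_r),

the standard competitive LV form with each clone's crowding normalised by
its own carrying capacity. `α_sr` is the per-capita effect of the resistant
clone on the sensitive one; `α_rs` the reverse; the ratio `α_rs/α_sr`
quantifies competitive asymmetry and is invariant to rescaling the signal
units (fluorescence channels are taken as proportional to per-clone
abundance with the scale absorbed into the per-channel `K`; channel
cross-talk is assumed zero). When `α_sr α_rs < 1` the system has the
coexistence equilibrium `x*_s = K(1 − α_sr)/(1 − α_sr α_rs)`,
`x*_r = K(1 − α_rs)/(1 − α_sr α_rs)` (equal `K`), used as an analytic
oracle in the tests.

Integration uses adaptive Runge–Kutta (`solve_ivp`, rtol 1e−8, atol 1e−10);
a fixed-step classic RK4 is available for bit-reproducibility checks.

**Fitting.** Three stages:

1. per-clone `(r, K, x0)` from monoculture logistic fits;
2. `(α_sr, α_rs)` plus one total inoculum per co-culture (split by the
   known seeding fractions, which the curve dialect encodes in the
   condition label, e.g. `co_25_75`) by least squares on all co-culture
   channels jointly across seeding ratios;
3. joint refinement of all parameters on monoculture and co-culture curves
   at once (default; stage-2-only available via `joint_refine=False`).

The joint refinement is not cosmetic. A sensitivity analysis at the default
scenario shows `∂α_sr/∂r_s ≈ −600`: a 1% error in a plugged-in monoculture
growth rate shifts `α_sr` by ≈0.19 — as large as the coefficient itself —
so the two-stage plug-in estimate is unstable at realistic noise, while the
joint fit propagates the monoculture information coherently.

Residuals are taken on the **log scale** because the measurement noise of
confluence/area readouts is multiplicative (constant CV); this is weighted
least squares with the statistically appropriate weights, makes the fit
scale-invariant, and changes nothing in the noiseless limit.

**Identifiability.** When the co-culture channels are indistinguishable from
monocultures the coefficients collapse to the zero boundary of the parameter
box; the fit then reports `converged_ = False` with a diagnostic, as it does
when the residuals are insensitive to the coefficients (vanishing Jacobian
columns).

**Uncertainty.** Residual-resampling bootstrap: log-residuals are resampled
with replacement within each curve, added back to the fitted trajectories,
and the full fit is re-run warm-started at the point estimate (default 1000
resamples; per-resample streams are spawned from the seed so shorter and
longer runs share their leading resamples). The violin/quantile summary is
this package's choice of uncertainty method; the estimator's sampling
distribution is right-skewed because the small coefficient `α_sr` enters
the ratio's denominator.

**Precision limit.** At the default study conditions (5% CV noise, 4
replicates, 12 h sampling to 264 h) the Fisher information bounds the
standard deviation of the recovered ratio at ≈0.33 around the true 3.5 —
about 10% relative — and the implemented estimator attains ≈0.37 with a
small (+0.1–0.2) finite-noise bias that vanishes as the noise CV shrinks.
Per-dataset accuracy much better than ~15% therefore cannot be guaranteed
by any estimator under these conditions; the tests assert recovery at the
level the information content supports, and the acceptance script reports
the mean over several independently generated experiments to give the
estimator's central value rather than a single noisy draw.

## Dose–response: IC50, GR metrics, mixtures

Viability (fraction of vehicle control) versus dose is fitted with the
four-parameter logistic
`v(d) = bottom + (top − bottom)/(1 + (d/ec50)^hill)`. Two potency
conventions are reported separately: the curve midpoint `ec50_rel`, and the
**absolute IC50** — the dose where the fitted curve crosses 0.5 of control —
which is the convention used throughout (matching "<50% from control"
screening language); the IC50 is flagged undefined when the fitted curve
never reaches 0.5. Fold-resistance between clone groups is the ratio of
arithmetic group-mean IC50s (undefined values excluded with a warning),
reported to one decimal by default.

Because a slow-dividing clone accumulates fewer drug-affected divisions in a
fixed 72 h assay, raw IC50s confound potency with division rate. The
growth-rate-corrected value

    GR(c) = 2^( log2(x_c/x0) / log2(x_ctrl/x0) ) − 1

(treated count `x_c`, time-of-treatment count `x0`, vehicle control
`x_ctrl`) rescales the effect to a per-division basis: GR = 1 means no
effect, 0 complete cytostasis, negative values net cell loss. GR dose
curves are fitted with `GR(c) = gr_inf + (1 − gr_inf)/(1 + (c/gec50)^h)`
and the GR50 solved from `GR = 0.5`. A curve is flagged **UTBD** ("unable
to be determined") instead of given a GR50 when the fitted curve stays
within 0.1 of 1 over the tested range (this package's operationalisation of
a flat GR curve) or never crosses 0.5 in range. The defining invariance —
clones differing only in division rate share a GR50 while their absolute
IC50s diverge — is verified in the test suite by construction.

Mixture response assumes independent action:
`S_mix(d) = (1 − f)·S_neg(d) + f·S_pos(d)` for resistant fraction `f`,
with the mixture IC50 found by bisection over a bracket two decades beyond
the tested doses. Under this model the mixture IC50 is strictly monotone in
`f` — a useful contrast, since measured mixtures that match the
pure-sensitive IC50 indicate that killing the sensitive compartment
dominates the endpoint rather than independent survival. Replicate-level
IC50 groups (pure clones and mixtures) are compared with two-sided Student
t-tests against both pure references; `p ≥ 0.05` is reported NS. The test
behind published two-clone-per-group comparisons is not generally stated in
study reports; the replicate-level t-test is exposed and the ambiguity
documented here.

## Screen normalization and hit calling

Per-well nuclear counts are normalised as fold change to the **median of
the same plate's negative-control wells**, which cancels any per-plate
multiplicative batch factor exactly (the suite asserts hit calls are
invariant to plate distortions). Fold changes are then robust Z-scored,
`z = (x − median)/(1.4826 · MAD)` (the 1.4826 makes the MAD consistent for
a normal scale), against the reference population of all compound wells per
cell line — controls excluded so the compound distribution is not diluted.
A zero MAD falls back to the standard deviation with a flag; zero both ways
yields all-zero scores, flagged.

Decision rules:

* **primary hit**: fold change < 0.5 at ≥1 dose point in *every* required
  cell line (a conjunction — a compound inert in one line fails);
* **validation nomination**: robust Z < −2 at ≥2 dose points, evaluated by
  default on the mean-across-cell-lines profile per dose (a per-line mode is
  available; how lines are combined is not standardised in study reports).

Default dose ladders are the 3-point primary (5, 0.5, 0.05 µM) and 6-point
validation (10, 5, 2.25, 0.5, 0.225, 0.05 µM) designs.

## Morphology features

Per-cell feature tables are robust-Z-scored to the median and MAD of the
reference (sensitive) population. Features whose reference MAD is zero or
negligible relative to the dataset's typical feature MAD (< 1e−6 of the
median positive MAD) are centred but not scaled, so near-constant
("inactive") measurements are not inflated by their own vanishing scale and
are subsequently removed by the variance floor.

Reduction iterates to a fixed point: drop features with variance below
`var_floor` (default 1e−3 on the robust-Z scale; no published threshold
exists, and on that scale active features have variance near 1); then,
while any retained pair exceeds `|r| = 0.85`, drop one member of the
worst-correlated pair — the one with the higher mean absolute correlation
to all other retained features, ties broken by name (a deterministic
tie-break; the ordering is not standardised). Every removal is logged with
its reason and partner; the retained set provably contains no pair above the
cut and re-running the reducer on its own output removes nothing.

Group differences are tested per feature with two-sided Welch t-tests on
per-cell values (per-cell rather than per-well testing matches the very
small p-values reported in imaging studies, implying `n` in the hundreds of
cells; the unit-of-analysis choice is documented, not hidden). Raw and
Benjamini–Hochberg-adjusted p-values are both reported. Degenerate features
(zero variance in both groups) get `p = 1` with a flag.

## Synthetic data: what it emulates, what it does not

The generators produce, from a single integer seed (all draws via
`numpy.random.default_rng`; identical spec + seed gives byte-identical
tables, and every table ships with a ground-truth sidecar that regenerates
it):

* logistic growth curves sampled every 12 h (default) to 264 h, 4
  replicates, with multiplicative Gaussian noise `x·(1 + ε)`,
  `ε ~ N(0, cv²)` truncated at −0.9 to keep signals positive (measurement
  noise magnitude is rarely published; 5% CV is a realistic default for
  confluence imaging and is configurable);
* LV co-cultures at 25:75 / 50:50 / 75:25 seeding, the co-culture seeded at
  the mean of the two monoculture inocula and split by the ratio — the
  same-total-density protocol of mixed-seeding experiments;
* 384-well plates (one per cell line, 16 negative-control wells, lognormal
  per-plate batch factors, planted hits as per-dose true viabilities, 10%
  count CV); counts are real-valued — DAPI nuclear counts are large enough
  that Gaussian noise suffices and Poisson rounding would add nothing;
* 4PL viability tables with control and time-zero rows (so GR metrics are
  computable) and fraction-weighted mixtures;
* morphology tables: unit-variance Gaussian features with correlated blocks
  (target Pearson r), near-constant inactive features, and group shifts in
  scaled-MAD units.

Shipped presets encode the study conditions: a sensitive clone with 22 h
doubling time and a resistant clone with 44 h (`r = ln 2/t_d`, `K = 100`
signal units), inocula set so the noiseless curves reach 50% of capacity at
the observed mean times (62.46 h and 135.38 h), giving `x0 = 12.26` and
`10.60` — the realistic ~10% starting confluence of a 1000–3000 cells/well
seeding. The default competition preset uses `α_sr = 0.2, α_rs = 0.7`
(ratio 3.5, the asymmetry the analyses are asked to recover) with equal
capacities. The inoculum choice matters beyond realism: identifiability
analysis shows the competition ratio is nearly unidentifiable within a
264 h horizon when cultures start at 1% of capacity, and well determined at
~12%.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: spatial well effects and edge artifacts,
channel cross-talk and fluorescence bleed-through, media-change transients,
contact inhibition deviating from logistic form, heavy-tailed or correlated
measurement errors, and cell-line heterogeneity beyond the preset
parameters. Results on real screens should be sanity-checked against the
control summaries and removal logs the tools emit.

## Numerical choices and edge cases

* All optimiser tolerances are set to 1e−12 (bootstrap refits 1e−10 with a
  capped iteration budget, warm-started at the point estimate).
* Logistic and 4PL fits report `converged = False` rather than raising when
  the optimiser fails or a parameter lands on a bound; flat curves, <5 time
  points, <4 doses, absent control wells, thresholds outside `(x0, K)` and
  invalid mixture fractions raise `ValueError` with the offending quantity.
* The mixture IC50 bisection uses `brentq` to near machine precision; an
  absent crossing returns an undefined-flagged result, not an exception.
* CSV readers validate the dialect strictly (monotone times per series,
  non-negative finite values) and cite 1-based line numbers on failure.
* Tables are written with 6 significant digits; comparisons happen in
  memory at full precision.

## Known limitations

* The LV fit supports exactly two clones; no treatment-coupled dynamics
  (adaptive-therapy scheduling is out of scope).
* No B-score/spatial correction in the screen module and no synergy
  modelling in dose–response.
* The bootstrap quantifies sampling noise given the model; it does not
  detect structural misfit (inspect residuals and the rss attributes).
* Feature reduction is greedy; it guarantees the pairwise correlation bound
  but not a globally optimal retained set.
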