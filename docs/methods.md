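# Methods

## Setting and model

The package targets two-arm time-to-progression data in which the treated
arm's hazard is not proportional to the control's: maintenance therapies
with a scheduled stop can show an early benefit, attenuation, and a
post-discontinuation excess of risk.  The generative model used throughout
testing and the examples is a piecewise-exponential trial:

- the control arm progresses with piecewise-constant daily rate λ₀(t);
- the treated arm's rate is λ₀(t)·r(t) with r(t) piecewise constant;
- censoring is independent exponential dropout plus an administrative
  cutoff; covariates, when present, are categorical and act
  multiplicatively on the hazard (log-linear) and, optionally, on the
  log-odds of treatment assignment (measured confounding).

Event times are sampled exactly by inverting the piecewise-linear
cumulative hazard (no discretization), so closed-form oracles are
available for every downstream estimate: S(t) = exp(−Λ(t)), the true r(t),
and exact marginal (counterfactual) restricted means obtained by averaging
per-stratum survival over the covariate distribution.

### Default scenario

The shipped `icon7_like` scenario emulates a first-line maintenance trial
with a 12-month protocol: control rate 0.00134/day (median
progression-free time ≈ 17 months), r(t) = 0.6 on days [0, 180), 0.85 on
[180, 365), 1.0 on [365, 395), 1.4 on [395, 720), 1.0 after; exponential
dropout at 0.0003/day and administrative censoring at day 1095.  The r(t)
profile reproduces the qualitative benefit → attenuation → rebound shape
reported for such trials; the censoring values are declared defaults (the
real censoring process of any particular cohort is not identifiable from
published curves).  These are the package's fixed study conditions for
examples and tests, not estimates of any real trial.

## Estimators

**Kaplan–Meier.** Product-limit with the events-before-censorings tie
rule; subjects censored at t remain at risk for events at t.  The step
function is right-continuous and is always evaluated through
`survival_at`; lookups beyond the last observed time return the last value
with an extrapolation flag.  Greenwood's formula supplies the pointwise
variance.  Case weights are supported for the IPW-adjusted estimator, in
which case Greenwood is only a working quantity and inference bootstraps.

**Risk curves.** `risk(t) = S(t) − S(t + w)` with window w = 30 days;
the conditional variant divides by S(t).  The absolute form follows the
plain reading of "the decrease on the survival curve over the next 30
days" and is the default; the conditional form is provided because the
ratio of conditional risks equals r(t) up to O(w·λ) terms, whereas the
ratio of absolute risks is additionally scaled by S₁(t)/S₀(t) (about
+11 % at the rebound peak of the default scenario).  Recovery-of-truth
analyses therefore use conditional mode.

**Relative risk.** RR(t) = risk₁(t)/risk₀(t), undefined (with reason
codes) where either risk is zero — zero-denominator, zero-numerator — or
where either input is unavailable.  Interpreting "either is zero" as
either arm's risk follows the method's stated incalculability rule.

**Smoothing.** Centered simple moving average over [t−60, t+60]
(121 days including t), truncated at the grid edges; missing values are
excluded from each window mean rather than propagated, so isolated
incalculable days do not erase the curve.  The smoother is linear,
mean-preserving on fully observed constant-extended input, and never
produces values outside the input range.

**Rebound.** On the smoothed RR curve, the first day at or after the
scheduled discontinuation where RR > 1 on at least 30 consecutive
non-missing days.  The run-length requirement suppresses single-day noise
crossings; 30 days was chosen once as roughly the window length.  The
report includes the pre-discontinuation minimum and post-discontinuation
peak; an all-missing post segment yields "indeterminate".

**RMST.** Exact area under the KM step function on [0, τ]; variance by
the standard integrated-Greenwood formula
Var = Σᵢ Aᵢ² dᵢ/(nᵢ(nᵢ−dᵢ)) with Aᵢ the remaining area past tᵢ.
Default τ is the smaller of the two arms' largest observed times.
Difference CIs are normal-approximation on the natural scale; ratio CIs
use the delta method on the log scale; p-values are two-sided at α = .05.

**Landmark split.** "Before discontinuation": all subjects, follow-up
capped at the landmark L, later events recoded as censored at L.  "After":
subjects still at risk at L, follow-up re-zeroed.  This conditioning
construction is the primary reading of a before/after contrast; an
unconditional interval-RMST contrast on [L, τ] is exposed as
`interval_rmst_compare` because the two readings answer different
questions (conditional benefit among survivors vs total area difference).

**IPW.** Treatment-assignment probabilities from a binomial GLM with
logit link on dummy-coded categorical covariates (IRLS, tolerance 1e−8);
perfect separation is rejected with a diagnostic.  Stabilized weights
(arm share / fitted probability of the received arm) feed a weighted KM;
standard errors and CIs come from a nonparametric bootstrap (1000
resamples by default) that refits the assignment model in every resample,
propagating weight uncertainty.  A closed-form weighted variance was
deliberately omitted: the bootstrap covers both sampling and weight
estimation error with one mechanism.

**PH diagnostic.** Hazard-ratio constancy is checked by partitioning
follow-up at user-chosen cut days, computing events and person-time per
period and arm, and testing one-ratio-per-period against a common ratio by
a Poisson person-time likelihood ratio on χ²(K−1).  This piecewise
person-time construction is self-contained and directly targets the
quantity the risk curves visualize (a time-varying ratio); it is not a
Schoenfeld-residual test.  Periods with zero person-time in either arm are
flagged, excluded, and the degrees of freedom reduced.

## Digitization

Input is an already-extracted pixel polyline per curve plus axis anchors
(time 0 and the 12- or 24-month tick on x; 0 % and 100 % on y); no image
processing is performed.  Calibration is affine per axis; month anchors
convert at 365/12 days per month.  Per-day survival uses previous-value
(step) interpolation; spans where consecutive points are more than
max(3 days, 3× the median sampling interval) apart are bridged linearly
and flagged `interpolated` — the automated substitute for manually
completing occluded curve segments, flagged per day so its influence can
be audited.  Days past the last point carry the last value, flagged
`extrapolated`.  Tracing noise is removed by a running minimum
(monotonicity repair) and the series is clipped to [0, 1]; S(0) is snapped
to 1 only when the traced start is within 2 % of 1, otherwise a warning is
raised and the value kept.  The companion rasterizer samples a step
function into one polyline point per pixel column with optional uniform
vertical jitter and deleted spans, giving a round-trip oracle: with ≥ 1
pixel column per day, recovery error is bounded by one y-pixel of survival
fraction plus one day's step quantization.

## Problem sizes and numerical choices

Simulated checks use n = 2000 per arm for curve-level analyses, n = 5000
per arm for the confounding study, 500 replicates at n = 200 per arm for
null calibration, and 1000 bootstrap resamples for landmark CIs — sizes at
which the qualitative structure (rebound onset, RMST reversal, IPW
recovery) is stable while the whole suite runs in minutes.  The smoothed
RR curve itself remains noisy at n = 2000 per arm: beyond day ~500 a
30-day window holds ≈ 40–55 events per arm and the ±60-day smoother spans
only ≈ 2.5 effectively independent windows, giving a pointwise standard
deviation of ≈ 0.13, so the pointwise curve should be read qualitatively
(trough → crossing → sustained excess) rather than as a precise estimate
of r(t); the rebound detector, which aggregates a 30-day run, is the
stable summary.

Ties in event times are real (integer-day data) and handled by the
events-first rule.  All RNG flows through a single seeded
`numpy.random.Generator` per call; identical seeds give byte-identical
outputs, and every pipeline run logs its configuration hash.

## What the generator does and does not emulate

It emulates: two-arm randomized (or confounded) assignment, piecewise
time-varying treatment effect with a scheduled stop, independent dropout,
administrative cutoff, categorical prognostic covariates, and
figure-quality noise (tracing jitter, occluded spans, axis quantization).
It does not emulate: covariate-dependent censoring, delayed entry,
interval-censored assessment schedules (real progression times cluster at
scan dates), competing mortality, or informative dropout.  Passing tests
therefore demonstrate correctness of the estimators under clean
assumptions, not robustness to those real-data features.

## Known limitations

- The digitized-curve workflow supports no formal inference: a published
  curve carries no per-day at-risk information, so risk and RR curves from
  images are descriptive.
- The landmark "after" contrast conditions on surviving the landmark and
  is not a randomized comparison if the arms differ compositionally at the
  landmark; the interval-RMST alternative is provided.
- The PH-constancy diagnostic depends on the chosen cut days.
- IPW removes only measured confounding, and the logistic model assumes
  additive log-odds effects.
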