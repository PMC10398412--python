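# progrisk

Time-dependent progression-risk analysis for two-arm survival data — built
for trials of maintenance therapies (such as anti-angiogenic agents in
ovarian cancer) whose effect is not constant over time, so that the usual
proportional-hazards summary misleads: an early benefit can attenuate and
then reverse into a period of *excess* risk after the scheduled end of
treatment (a rebound).

The package reconstructs per-day survival either from patient-level records
or from digitized Kaplan–Meier figures, and summarizes the arm contrast as
curves and restricted means rather than a single hazard ratio.

## What it computes

For survival curves S₁(t) (treated) and S₀(t) (control) on a daily grid:

- **Windowed progression risk** — the drop of the survival curve over the
  next 30 days, `risk(t) = S(t) − S(t+30)`, or conditionally
  `(S(t) − S(t+30)) / S(t)`;
- **Relative risk curve** — `RR(t) = risk₁(t) / risk₀(t)`, marked
  *incalculable* (with a reason code) wherever either risk is zero;
- **Smoothing** — a simple moving average over the 60 days before and
  after each day, skipping incalculable days;
- **Rebound detection** — the first post-discontinuation day at which the
  smoothed RR stays above 1 for a sustained run (30 days by default),
  plus the pre-discontinuation minimum and post-discontinuation peak;
- **RMST comparison** — restricted mean survival time
  `RMST(τ) = ∫₀^τ S(t) dt` per arm, with difference and ratio CIs, overall
  and split at a landmark (the scheduled treatment stop): follow-up is
  capped at the landmark for the *before* contrast and re-zeroed among
  subjects still at risk for the *after* contrast;
- **IPW adjustment** — stabilized inverse-probability-of-treatment weights
  from a logistic assignment model, weighted KM, and bootstrap inference;
- **Digitization** — calibration of traced KM-figure pixel polylines
  (axis anchors at months 0 and 12/24, survival 0 and 100 %) into per-day
  survival with gap interpolation and monotonicity repair;
- **Simulation** — a piecewise-exponential two-arm trial generator with a
  time-varying relative hazard r(t), optional confounded categorical
  covariates, and a KM-figure rasterizer, so the whole pipeline is testable
  end to end against known truth.

## Worked example

```python
import progrisk as pr

scenario = pr.icon7_like_scenario()        # benefit -> attenuation -> rebound
trial = pr.simulate_trial(scenario, None, n_per_arm=2000, seed=0)

series = {a: pr.km_estimate(trial, a).to_daily_series(1000) for a in (0, 1)}
risk = {a: pr.progression_risk(series[a], 30, pr.CONDITIONAL) for a in (0, 1)}
rr = pr.smooth(pr.relative_risk(risk[1], risk[0]), 60)
print(pr.detect_rebound(rr, discontinuation_day=365))

pre, post = pr.landmark_split(trial, 365.0)
print(pr.rmst_compare(trial, pr.default_tau(trial)).ratio)
```

Running the numbered drivers under `analysis/` on this simulated trial
prints (seed 0):

```
rebound detected: True
onset day: 365 | peak smoothed RR: 1.85 (day 676)
pre-discontinuation minimum RR: 0.62 (day 78)

overall                ratio 1.003 (95% CI 0.962-1.046)  p=0.888
pre_discontinuation    ratio 1.066 (95% CI 1.043-1.089)  p=2.8e-08
post_discontinuation   ratio 0.848 (95% CI 0.805-0.890)  p=1.13e-10
```

Read: during treatment the treated arm's 30-day progression risk is ~40 %
below control (smoothed RR 0.62 at the trough); after the scheduled stop at
day 365 the smoothed RR rises above 1 and peaks near 1.85, and the RMST
ratio flips from 1.07 (better) before the landmark to 0.85 (worse) after
it, while the overall contrast — and the log-rank test (p = 0.37) — see
almost nothing because the two periods cancel.  The IPW driver shows the
same machinery removing deliberate confounding: naive ratio 0.97 vs
counterfactual truth 1.12, adjusted estimate 1.11 with covariate imbalance
reduced to < 0.01 total variation.

A command-line front end wraps the same steps:

```bash
progrisk simulate --n-per-arm 2000 --seed 0 --out trial.csv
progrisk riskcurve --records trial.csv --out-dir out/
progrisk rmst --records trial.csv --landmark 365
```

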