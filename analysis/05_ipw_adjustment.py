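"""Covariate adjustment by stabilized inverse-probability weighting.

A confounded variant of the trial: advanced stage and residual disease
raise both the progression hazard and the odds of receiving treatment, so
the naive RMST ratio understates the benefit.  The counterfactual truth is
computed exactly from the generating model; stabilized IPW should recover
it and balance the covariates.
"""

import json
from pathlib import Path

import progrisk as pr

ROOT = Path(__file__).resolve().parents[1]
SEED = 0


def main() -> None:
    scenario = pr.icon7_like_scenario()
    cov = pr.confounded_covariate_model()
    trial = pr.simulate_trial(scenario, cov, n_per_arm=5000, seed=SEED + 4)
    tau = 1000.0

    truth = pr.marginal_true_rmst_ratio(scenario, cov, tau)
    naive = pr.rmst_compare(trial, tau)
    ipw = pr.fit_ipw(trial, cov.names)
    adjusted = pr.adjusted_rmst_compare(trial, ipw, tau, n_boot=200, seed=SEED + 5)
    balance = pr.covariate_balance(trial, cov.names, ipw.weights)

    payload = {
        "tau_days": tau,
        "true_marginal_rmst_ratio": truth,
        "unadjusted_ratio": naive.ratio,
        "adjusted_ratio": adjusted.ratio,
        "adjusted_ratio_ci": list(adjusted.ratio_ci),
        "max_weighted_imbalance_tv": float(balance["tv_distance"].max()),
        "weight_range": [ipw.diagnostics["weight_min"], ipw.diagnostics["weight_max"]],
    }
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "ipw_adjustment.json").write_text(
        json.dumps(payload, indent=2) + "\n")

    print("true marginal RMST ratio:  %.3f" % truth)
    print("unadjusted estimate:       %.3f (bias %.3f)"
          % (naive.ratio, naive.ratio - truth))
    print("IPW-adjusted estimate:     %.3f (95%% CI %.3f-%.3f)"
          % (adjusted.ratio, *adjusted.ratio_ci))
    print("max weighted covariate imbalance (TV): %.4f"
          % payload["max_weighted_imbalance_tv"])
    print("results -> results/ipw_adjustment.json")


if __name__ == "__main__":
    main()
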