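import numpy as np
import pandas as pd
import pytest

import progrisk as pr
from conftest import make_records, quadrature_rmst, random_survival_instance


class TestRmst:
    def test_flat_survival_gives_tau(self):
        sf = pr.km_estimate(make_records([25, 25], [0, 0], [0, 0]))
        est, se = pr.rmst(sf, 20.0)
        assert est == 20.0 and se == 0.0

    def test_rectangle_areas(self):
        # S = 1 on [0,10), 0.5 on [10,20): area to 20 is 10 + 5 = 15
        sf = pr.km_estimate(make_records([10, 20], [1, 1], [0, 0]))
        est, _ = pr.rmst(sf, 20.0)
        assert est == pytest.approx(15.0, abs=1e-12)

    def test_step_area_equals_quadrature_of_survival_at(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            df = random_survival_instance(rng)
            sf = pr.km_estimate(df)
            tau = float(sf.max_time)
            est, _ = pr.rmst(sf, tau)
            assert est == pytest.approx(quadrature_rmst(sf, tau), abs=1e-9)

    def test_matches_lifelines_restricted_mean(self):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        df = random_survival_instance(np.random.default_rng(11), n_max=25)
        sf = pr.km_estimate(df)
        tau = float(sf.max_time)
        kmf = KaplanMeierFitter().fit(df["time"], df["event"])
        assert pr.rmst(sf, tau)[0] == pytest.approx(
            float(restricted_mean_survival_time(kmf, t=tau)), abs=1e-9
        )

    def test_monotone_in_tau(self, icon7_trial):
        sf = pr.km_estimate(icon7_trial, 0)
        taus = [100.0, 300.0, 600.0, 900.0]
        values = [pr.rmst(sf, t)[0] for t in taus]
        assert np.all(np.diff(values) > 0)

    def test_tau_beyond_followup_rejected(self):
        sf = pr.km_estimate(make_records([10, 20], [1, 1], [0, 0]))
        with pytest.raises(ValueError, match="tau"):
            pr.rmst(sf, 25.0)


class TestRmstCompare:
    def test_identical_arms_are_null(self):
        one = make_records([5, 10, 15, 20], [1, 1, 0, 1], [0] * 4)
        two = one.copy()
        two["arm"] = 1
        res = pr.rmst_compare(pd.concat([one, two], ignore_index=True))
        assert res.ratio == pytest.approx(1.0, abs=1e-12)
        assert res.difference == pytest.approx(0.0, abs=1e-12)
        assert res.ratio_p == pytest.approx(1.0, abs=1e-9)

    def test_benefit_scenario_recovers_true_ratio(self):
        sc = pr.HazardScenario(
            control_rates=((0.0, 0.00134),), relative_hazard=((0.0, 0.6),),
            censor_rate=0.0003, admin_cutoff_day=1095.0,
        )
        df = pr.simulate_trial(sc, None, n_per_arm=2000, seed=8)
        tau = 1000.0
        res = pr.rmst_compare(df, tau)
        truth = pr.marginal_true_rmst_ratio(sc, None, tau)
        se_ratio = res.ratio * np.sqrt(
            (res.se_by_arm[0] / res.rmst_by_arm[0]) ** 2
            + (res.se_by_arm[1] / res.rmst_by_arm[1]) ** 2
        )
        assert abs(res.ratio - truth) < 3 * se_ratio

    def test_ratio_invariant_to_time_rescaling(self, icon7_trial):
        res_days = pr.rmst_compare(icon7_trial, 900.0)
        months = icon7_trial.copy()
        months["time"] = months["time"] / 30.44
        res_months = pr.rmst_compare(months, 900.0 / 30.44)
        assert res_days.ratio == pytest.approx(res_months.ratio, rel=1e-9)


class TestLandmarkSplit:
    def test_landmark_zero_post_equals_input(self, icon7_trial):
        _, post = pr.landmark_split(icon7_trial, 0.0)
        pd.testing.assert_frame_equal(
            post.reset_index(drop=True), icon7_trial.reset_index(drop=True)
        )

    def test_event_after_landmark_recoded(self):
        df = make_records(
            [400.0, 500.0, 300.0, 600.0, 700.0], [1, 0, 1, 1, 0], [0, 0, 1, 1, 1]
        )
        pre, post = pr.landmark_split(df, 365.0)
        subj = pre.iloc[0]
        assert subj["time"] == 365.0 and subj["event"] == 0
        moved = post[post["id"] == "S0"].iloc[0]
        assert moved["time"] == pytest.approx(35.0) and moved["event"] == 1
        assert "S2" not in set(post["id"])  # event before landmark: not at risk

    def test_pre_and_post_areas_reconstruct_complete_data_mean(self):
        # uncensored complete data: E[min(T, tau)] splits exactly at the landmark
        rng = np.random.default_rng(5)
        times = rng.exponential(300.0, size=400) + 1.0
        df = make_records(times, np.ones(400), np.zeros(400, dtype=int))
        tau, L = 600.0, 200.0
        whole, _ = pr.rmst(pr.km_estimate(df), tau)
        pre, post = pr.landmark_split(df, L)
        pre_area, _ = pr.rmst(pr.km_estimate(pre), L)
        at_risk_frac = (times > L).mean()
        post_sf = pr.km_estimate(post)
        post_area, _ = pr.rmst(post_sf, tau - L)
        assert whole == pytest.approx(pre_area + at_risk_frac * post_area, rel=1e-9)

    def test_landmark_outside_followup_rejected(self, icon7_trial):
        with pytest.raises(ValueError):
            pr.landmark_split(icon7_trial, 5000.0)


class TestIntervalRmst:
    def test_interval_contrast_from_zero_equals_overall(self, icon7_trial):
        overall = pr.rmst_compare(icon7_trial, 800.0)
        interval = pr.interval_rmst_compare(icon7_trial, 0.0, 800.0)
        assert interval.ratio == pytest.approx(overall.ratio, rel=1e-12)


class TestIpw:
    def test_randomized_data_gives_unit_weights(self, icon7_scenario):
        df = pr.simulate_trial(
            icon7_scenario, pr.randomized_covariate_model(), n_per_arm=1000, seed=10
        )
        ipw = pr.fit_ipw(df, ["stage", "debulk", "age", "histology"])
        # null model: deviations from the arm share are pure sampling noise
        assert np.abs(ipw.propensity - 0.5).max() < 0.12
        assert np.abs(ipw.weights - 1.0).max() < 0.3

    def test_known_assignment_log_odds_recovered(self):
        model = pr.CovariateModel(
            categories={"stage": {"early": 0.5, "advanced": 0.5}},
            assignment_log_odds={"stage": {"advanced": 1.0}},
        )
        sc = pr.HazardScenario(
            control_rates=((0.0, 0.002),), relative_hazard=((0.0, 1.0),),
            admin_cutoff_day=1000.0,
        )
        df = pr.simulate_trial(sc, model, n_per_arm=2500, seed=12)
        ipw = pr.fit_ipw(df, ["stage"])
        slope = [v for k, v in ipw.coefficients.items() if "stage" in k]
        assert len(slope) == 1
        assert abs(abs(slope[0]) - 1.0) < 0.15

    def test_weights_balance_covariates(self, icon7_scenario):
        df = pr.simulate_trial(
            icon7_scenario, pr.confounded_covariate_model(), n_per_arm=2500, seed=13
        )
        covs = ["stage", "debulk", "age", "histology"]
        ipw = pr.fit_ipw(df, covs)
        assert np.all(ipw.weights > 0)
        balance = pr.covariate_balance(df, covs, ipw.weights)
        assert balance["tv_distance"].max() <= 0.02

    def test_perfect_separation_rejected(self):
        df = make_records([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1],
                          stage=["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            pr.fit_ipw(df, ["stage"])

    def test_unknown_covariate_rejected(self, icon7_trial):
        with pytest.raises(ValueError):
            pr.fit_ipw(icon7_trial, ["nonexistent"])


class TestAdjustedRmst:
    def test_unit_weights_reproduce_unadjusted_points(self, icon7_trial):
        tau = 900.0
        plain = pr.rmst_compare(icon7_trial, tau)
        boot = pr.adjusted_rmst_compare(icon7_trial, None, tau, n_boot=20, seed=1)
        assert boot.rmst_by_arm[0] == pytest.approx(plain.rmst_by_arm[0], abs=1e-12)
        assert boot.rmst_by_arm[1] == pytest.approx(plain.rmst_by_arm[1], abs=1e-12)

    def test_adjustment_on_randomized_data_changes_little(self, icon7_scenario):
        df = pr.simulate_trial(
            icon7_scenario, pr.randomized_covariate_model(), n_per_arm=2000, seed=14
        )
        tau = 900.0
        covs = ["stage", "debulk", "age", "histology"]
        plain = pr.rmst_compare(df, tau)
        adj = pr.adjusted_rmst_compare(df, pr.fit_ipw(df, covs), tau, n_boot=30, seed=2)
        assert abs(adj.ratio - plain.ratio) < 0.02
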