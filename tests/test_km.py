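import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import progrisk as pr
from conftest import brute_force_km, hand_logrank, make_records, random_survival_instance


class TestKmEstimate:
    def test_all_events_product_limit(self):
        sf = pr.km_estimate(make_records([1, 2, 3], [1, 1, 1], [0, 0, 0]))
        assert np.allclose(sf.survival_after, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_gives_flat_one(self):
        sf = pr.km_estimate(make_records([1, 2, 3], [0, 0, 0], [0, 0, 0]))
        assert sf.survival_at(3.0) == 1.0

    def test_events_precede_censorings_at_ties(self):
        # censored-at-1 subject is still at risk for the event at 1
        sf = pr.km_estimate(make_records([1, 1, 2], [1, 0, 1], [0, 0, 0]))
        assert sf.survival_at(1) == pytest.approx(2 / 3)
        assert sf.survival_at(2) == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pr.km_estimate(make_records([1], [1], [1]), arm_filter=0)

    def test_matches_brute_force_enumeration_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            df = random_survival_instance(rng)
            sf = pr.km_estimate(df)
            oracle = brute_force_km(df["time"].tolist(), df["event"].tolist())
            assert len(oracle) == len(sf.event_times)
            for (t, s), t2, s2 in zip(oracle, sf.event_times, sf.survival_after):
                assert t == t2 and s == s2  # bitwise identical product

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        df = random_survival_instance(rng, n_max=25)
        sf = pr.km_estimate(df)
        kmf = KaplanMeierFitter().fit(df["time"], df["event"])
        for t in sf.event_times:
            assert sf.survival_at(float(t)) == pytest.approx(
                float(kmf.predict(t)), abs=1e-12
            )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_survival_and_growing_variance(self, seed):
        df = random_survival_instance(np.random.default_rng(seed))
        sf = pr.km_estimate(df)
        assert np.all(np.diff(sf.survival_after) <= 1e-12)
        assert np.all(sf.survival_after >= -1e-12) and np.all(sf.survival_after <= 1)
        # Greenwood cumulative sum only grows while S > 0
        pos = sf.survival_after > 0
        gw = sf.greenwood_var[pos] / sf.survival_after[pos] ** 2
        assert np.all(np.diff(gw) >= -1e-15)


class TestSurvivalAt:
    def test_day_zero_is_one(self):
        sf = pr.km_estimate(make_records([10], [1], [0]))
        assert sf.survival_at(0.0) == 1.0

    def test_right_continuous_step(self):
        sf = pr.km_estimate(make_records([10, 12], [1, 0], [0, 0]))
        assert sf.survival_at(9.99) == 1.0
        assert sf.survival_at(10.0) == 0.5

    def test_extrapolation_flagged_beyond_followup(self):
        sf = pr.km_estimate(make_records([10, 12], [1, 0], [0, 0]))
        val, flag = sf.survival_at(50.0, with_flag=True)
        assert val == 0.5 and flag
        _, flag = sf.survival_at(11.0, with_flag=True)
        assert not flag

    def test_negative_day_rejected(self):
        sf = pr.km_estimate(make_records([10], [1], [0]))
        with pytest.raises(ValueError):
            sf.survival_at(-1.0)


class TestLogrank:
    def test_identical_arms_give_null(self):
        one = make_records([2, 4, 6, 8], [1, 1, 0, 1], [0, 0, 0, 0])
        two = one.copy()
        two["arm"] = 1
        import pandas as pd

        stat, p = pr.logrank(pd.concat([one, two], ignore_index=True))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_observed_minus_expected(self):
        df = make_records(
            [1, 4, 6, 2, 3, 5], [1, 1, 0, 1, 0, 1], [0, 0, 0, 1, 1, 1]
        )
        stat, _ = pr.logrank(df)
        assert stat == pytest.approx(hand_logrank(df), rel=1e-10)

    def test_invariant_to_time_unit_rescaling(self, icon7_trial):
        sub = icon7_trial.sample(300, random_state=1)
        stat_days, _ = pr.logrank(sub)
        months = sub.copy()
        months["time"] = months["time"] / 30.44
        stat_months, _ = pr.logrank(months)
        assert stat_days == pytest.approx(stat_months, rel=1e-9)

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError):
            pr.logrank(make_records([1, 2], [1, 1], [0, 0]))


class TestPhConstancy:
    def test_identical_arms_give_unit_ratios(self):
        import pandas as pd

        one = make_records([50, 150, 250, 350, 450], [1, 1, 1, 0, 1], [0] * 5)
        two = one.copy()
        two["arm"] = 1
        diag = pr.ph_constancy_test(pd.concat([one, two], ignore_index=True), [200.0])
        kept = diag.table[~diag.table["excluded"]]
        assert np.allclose(kept["hr"], 1.0)
        assert diag.statistic == pytest.approx(0.0, abs=1e-6)

    def test_detects_hazard_ratio_change(self):
        sc = pr.HazardScenario(
            control_rates=((0.0, 0.005),),
            relative_hazard=((0.0, 0.5), (200.0, 1.5)),
            admin_cutoff_day=600.0,
        )
        df = pr.simulate_trial(sc, None, n_per_arm=1000, seed=9)
        diag = pr.ph_constancy_test(df, [200.0])
        assert diag.p_value < 1e-4
        hr = diag.table.set_index("period")["hr"]
        assert hr[0] < 1 < hr[1]

    def test_null_rejection_rate_near_alpha(self):
        sc = pr.HazardScenario(
            control_rates=((0.0, 0.003),), relative_hazard=((0.0, 1.0),),
            admin_cutoff_day=800.0,
        )
        rej = 0
        reps = 120
        for i in range(reps):
            df = pr.simulate_trial(sc, None, n_per_arm=150, seed=20_000 + i)
            rej += pr.ph_constancy_test(df, [250.0]).p_value < 0.05
        assert 0.01 <= rej / reps <= 0.12

    def test_unsorted_cuts_rejected(self, icon7_trial):
        with pytest.raises(ValueError):
            pr.ph_constancy_test(icon7_trial, [400.0, 200.0])
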