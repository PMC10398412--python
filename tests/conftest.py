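import numpy as np
import pandas as pd
import pytest

import progrisk as pr


def make_records(times, events, arms, **covs) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "id": [f"S{i}" for i in range(len(times))],
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "arm": np.asarray(arms, dtype=int),
        }
    )
    for k, v in covs.items():
        df[k] = v
    return df


def random_survival_instance(rng: np.random.Generator, n_max: int = 30) -> pd.DataFrame:
    """Small random censored sample with ties for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    times = rng.integers(1, 15, size=n).astype(float)  # integer times force ties
    events = rng.integers(0, 2, size=n)
    if events.sum() == 0:
        events[rng.integers(0, n)] = 1
    return make_records(times, events, np.zeros(n, dtype=int))


# --- independent oracles -----------------------------------------------------

def brute_force_km(times, events):
    """Product-limit by explicit risk-set enumeration (test oracle)."""
    pairs = list(zip(times, events))
    out = []
    s = 1.0
    for u in sorted({t for t, e in pairs if e == 1}):
        n = sum(1 for t, _ in pairs if t >= u)  # censored at u still at risk
        d = sum(1 for t, e in pairs if t == u and e == 1)
        s = s * (1 - d / n)
        out.append((u, s))
    return out


def quadrature_rmst(sf, tau):
    """Knot-aligned midpoint quadrature of survival_at (exact for steps)."""
    knots = [0.0] + [float(t) for t in sf.event_times if t < tau] + [float(tau)]
    return sum(
        sf.survival_at((a + b) / 2.0) * (b - a) for a, b in zip(knots, knots[1:])
    )


def hand_logrank(records: pd.DataFrame) -> float:
    """(O - E)^2 / V log-rank statistic by direct risk-set arithmetic."""
    t = records["time"].to_numpy()
    e = records["event"].to_numpy()
    a = records["arm"].to_numpy()
    O = E = V = 0.0
    for u in sorted(set(t[e == 1])):
        at = t >= u
        n, n1 = at.sum(), (at & (a == 1)).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & (a == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


# --- shared fixtures ---------------------------------------------------------

@pytest.fixture(scope="session")
def icon7_scenario():
    return pr.icon7_like_scenario()


@pytest.fixture(scope="session")
def icon7_trial(icon7_scenario):
    return pr.simulate_trial(icon7_scenario, None, n_per_arm=2000, seed=0)


@pytest.fixture(scope="session")
def icon7_series(icon7_trial):
    return {
        a: pr.km_estimate(icon7_trial, a).to_daily_series(1000) for a in (0, 1)
    }


@pytest.fixture()
def exponential_series():
    days = np.arange(0, 501)
    return pr.DailySurvivalSeries(day=days, S=np.exp(-0.01 * days))
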