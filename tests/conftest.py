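import datetime as dt

import numpy as np
import pandas as pd
import pytest

import runcontingent as rc

BASE = dt.date(2017, 1, 1)


def date(offset: int) -> dt.date:
    return BASE + dt.timedelta(days=int(offset))


def brute_force_dtw(a, b, step_pattern="symmetric2") -> float:
    """Exhaustive enumeration of every monotone warping path (oracle).

    Independent of the dynamic-programming implementation: walks the full
    path tree accumulating cost, diagonal steps weighted per step pattern.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    diag_w = 2.0 if step_pattern == "symmetric2" else 1.0
    c = np.abs(a[:, None] - b[None, :])
    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n:
            walk(i + 1, j, acc + c[i + 1, j])
        if j + 1 < m:
            walk(i, j + 1, acc + c[i, j + 1])
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc + diag_w * c[i + 1, j + 1])

    walk(0, 0, c[0, 0])
    return best[0]


def make_records(times, events, group="g", tags=None):
    """Survival records at integer day offsets from a common origin."""
    tags = tags or [f"{group}{i}" for i in range(len(times))]
    return [
        rc.SurvivalRecord(tag, group, BASE, date(t), bool(e))
        for tag, t, e in zip(tags, times, events)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic two-year study (12 + 12 fish)."""
    cfg = rc.SyntheticConfig(seed=11, n_fish_lower=12, n_fish_upper=12)
    return rc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition synthetic study (30 + 30 fish, seed 2024)."""
    return rc.simulate_cohort(rc.SyntheticConfig(seed=2024))
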