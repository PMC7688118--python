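"""Contingent-specific mortality: Z, Kaplan-Meier, and the Peto-Peto test.

Simulates post-run attrition for two contingents of realistic size (21 vs
45 fish) with daily hazards 4.9e-3 vs 1.0e-3, then estimates the
instantaneous loss rate Z by log-linear regression of extant counts,
one-year Kaplan-Meier survival with Greenwood standard errors, and the
Peto & Peto modified Gehan-Wilcoxon contrast between the groups.
"""

import datetime as dt

import numpy as np

from runcontingent import (
    SurvivalRecord,
    extant_counts,
    kaplan_meier,
    loss_rate,
    weighted_logrank,
)

rng = np.random.default_rng(8)
origin = dt.date(2017, 6, 1)


def cohort(n, hazard, group):
    times = np.ceil(rng.exponential(1 / hazard, n)).astype(int)
    return [
        SurvivalRecord(
            f"{group}{i}", group, origin,
            origin + dt.timedelta(days=int(min(t, 365))), bool(t <= 365),
        )
        for i, t in enumerate(times)
    ]


lower = cohort(21, 4.9e-3, "lower")
upper = cohort(45, 1.0e-3, "upper")

for name, records, true_z in (("lower", lower, 4.9e-3), ("upper", upper, 1.0e-3)):
    fit = loss_rate(extant_counts(records), period=(0, 365))
    s, se = kaplan_meier(records).at(365)
    print(
        f"{name}: Z = {fit.Z:.2e}/d (true {true_z:.1e}), "
        f"one-year survival {100 * s:.1f} +/- {100 * se:.1f}%"
    )

test = weighted_logrank(lower, upper, weights="peto-peto")
print(f"Peto-Peto chi-square = {test.statistic:.2f} (1 df), p = {test.p_value:.4f}")
print()
print("The early-departing, harder-fished contingent loses fish several")
print("times faster; the weighted test emphasises those early differences.")
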