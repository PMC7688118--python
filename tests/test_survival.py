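import datetime as dt

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

import runcontingent as rc
from conftest import BASE, date, make_records


class TestBuildRecords:
    def setup_method(self):
        self.start, self.end = date(0), date(365)

    def build(self, last_by_tag):
        origins = {t: self.start for t in last_by_tag}
        groups = {t: "g" for t in last_by_tag}
        return rc.build_records(last_by_tag, origins, groups, self.start, self.end)

    def test_last_seen_on_period_end_is_censored(self):
        (r,) = self.build({"a": self.end})
        assert not r.event and r.end_date == self.end

    def test_last_seen_well_before_end_is_event(self):
        (r,) = self.build({"a": date(265)})
        assert r.event and r.end_date == date(265)

    def test_within_censor_window_is_censored_at_period_end(self):
        (r,) = self.build({"a": date(340)})
        assert not r.event and r.end_date == self.end

    def test_event_dates_match_truth_on_synthetic_cohort(self, small_cohort):
        """Fish whose simulated death fell inside the analysis period are
        assigned event dates close to their true death dates."""
        truth = small_cohort.truth.set_index("tag_id")
        dets = small_cohort.detections.copy()
        dets["date"] = (dets["timestamp"] - pd.Timedelta(hours=5)).dt.date
        last = dets.groupby("tag_id")["date"].max().to_dict()
        start, end = dt.date(2017, 6, 1), dt.date(2018, 12, 31)
        exits = pd.to_datetime(truth["exit_y1"]).dt.date.to_dict()
        records = rc.build_records(
            last, exits, {t: "g" for t in last}, start, end
        )
        by_tag = {r.tag_id: r for r in records}
        checked = 0
        for tag, row in truth.iterrows():
            if row["death_date"] == "" or tag not in by_tag:
                continue
            death = dt.date.fromisoformat(row["death_date"])
            if (end - death).days <= 30:
                continue
            rec = by_tag[tag]
            assert rec.event
            # last shelf detection precedes death by a geometric waiting time
            assert 0 <= (death - rec.end_date).days <= 30
            checked += 1
        assert checked >= 3


class TestLossRate:
    def test_exact_exponential_recovered_to_machine_precision(self):
        t = np.arange(100)
        counts = pd.Series(66.0 * np.exp(-0.005 * t), index=t)
        fit = rc.loss_rate(counts)
        assert fit.Z == pytest.approx(0.005, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_counts_give_zero(self):
        fit = rc.loss_rate(pd.Series(10.0, index=np.arange(50)))
        assert fit.Z == pytest.approx(0.0, abs=1e-15)

    def test_too_few_dates_rejected(self):
        with pytest.raises(rc.ValidationError):
            rc.loss_rate(pd.Series([5.0, 4.0], index=[0, 1]))

    def test_zero_count_dates_excluded(self):
        counts = pd.Series([10.0, 5.0, 0.0, 2.0, 1.0], index=np.arange(5))
        fit = rc.loss_rate(counts)
        assert fit.n_dates == 4

    def test_monte_carlo_recovery_bias_below_sampling_error(self):
        """At n = 500 the fitted Z recovers a 4.9e-3 per-day hazard within
        10%, and its bias is below the between-replicate spread."""
        rng = np.random.default_rng(12)
        true_z = 4.9e-3
        estimates = []
        for _ in range(8):
            times = np.ceil(rng.exponential(1 / true_z, 500)).astype(int)
            records = make_records(
                np.minimum(times, 365), times <= 365
            )
            fit = rc.loss_rate(rc.extant_counts(records), period=(0, 365))
            estimates.append(fit.Z)
        estimates = np.array(estimates)
        assert abs(estimates.mean() - true_z) / true_z < 0.10
        assert abs(estimates.mean() - true_z) < estimates.std(ddof=1)


class TestKaplanMeier:
    def test_small_cohort_closed_form(self):
        """21 subjects, 9 deaths at distinct times, no censoring: survival
        12/21 = 57.1% with Greenwood (= binomial) SE 10.8%."""
        times = [30 + 20 * i for i in range(9)] + [365] * 12
        events = [True] * 9 + [False] * 12
        km = rc.kaplan_meier(make_records(times, events))
        s, se = km.at(365)
        assert round(100 * s, 1) == 57.1
        assert round(100 * se, 1) == 10.8

    def test_larger_cohort_closed_form(self):
        """45 subjects, 8 deaths, no censoring: 82.2% with SE 5.7%."""
        times = [30 + 20 * i for i in range(8)] + [365] * 37
        events = [True] * 8 + [False] * 37
        s, se = rc.kaplan_meier(make_records(times, events)).at(365)
        assert round(100 * s, 1) == 82.2
        assert round(100 * se, 1) == 5.7

    def test_no_events_survival_one(self):
        km = rc.kaplan_meier(make_records([100, 200], [False, False]))
        assert km.at(365) == (1.0, 0.0)

    def test_uncensored_equals_empirical_and_binomial_se(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            times = rng.integers(1, 300, n)
            km = rc.kaplan_meier(make_records(times, [True] * n))
            for t in (50, 150, 299):
                p_hat = np.mean(times > t)
                s, se = km.at(t)
                assert s == pytest.approx(p_hat, abs=1e-12)
                assert se == pytest.approx(np.sqrt(p_hat * (1 - p_hat) / n), abs=1e-12)

    def test_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(21)
        times = np.ceil(rng.exponential(150, 60)).astype(int)
        events = rng.random(60) < 0.7
        km = rc.kaplan_meier(make_records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        theirs = kmf.survival_function_.loc[km.times, "KM_estimate"].to_numpy()
        assert np.allclose(km.survival, theirs)

    def test_curve_nonincreasing_from_one(self):
        rng = np.random.default_rng(22)
        times = rng.integers(1, 200, 30)
        events = rng.random(30) < 0.5
        km = rc.kaplan_meier(make_records(times, events))
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.at(0)[0] <= 1.0


class TestWeightedLogrank:
    def two_groups(self, seed=30, n=35):
        rng = np.random.default_rng(seed)
        ta = np.ceil(rng.exponential(150, n)).astype(int)
        tb = np.ceil(rng.exponential(250, n)).astype(int)
        ea = rng.random(n) < 0.8
        eb = rng.random(n) < 0.8
        return (
            make_records(ta, ea, "a"),
            make_records(tb, eb, "b"),
            (ta, ea, tb, eb),
        )

    def test_identical_groups_statistic_zero(self):
        a = make_records([10, 20, 30], [True, True, False], "a")
        b = make_records([10, 20, 30], [True, True, False], "b")
        out = rc.weighted_logrank(a, b)
        assert out.statistic == pytest.approx(0.0, abs=1e-12)
        assert out.p_value == pytest.approx(1.0)

    def test_unit_weights_reduce_to_logrank_exactly(self):
        a, b, (ta, ea, tb, eb) = self.two_groups()
        mine = rc.weighted_logrank(a, b, weights="logrank")
        theirs = logrank_test(ta, tb, ea, eb)
        assert mine.statistic == pytest.approx(theirs.test_statistic, rel=1e-10)

    def test_peto_matches_lifelines(self):
        a, b, (ta, ea, tb, eb) = self.two_groups(seed=31)
        mine = rc.weighted_logrank(a, b, weights="peto-peto")
        theirs = logrank_test(ta, tb, ea, eb, weightings="peto")
        assert mine.statistic == pytest.approx(theirs.test_statistic, rel=1e-10)

    def test_no_events_rejected(self):
        a = make_records([10], [False], "a")
        b = make_records([20], [False], "b")
        with pytest.raises(rc.ValidationError):
            rc.weighted_logrank(a, b)

    def test_p_value_consistent_with_permutation_distribution(self):
        """Small two-group data: the chi-square p sits inside the spread of
        an exact permutation distribution of the weighted statistic."""
        rng = np.random.default_rng(33)
        times = np.array([12, 40, 55, 70, 90, 130, 200, 260, 20, 35, 60, 80, 150, 210, 300, 330])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1], bool)
        labels = np.array([True] * 8 + [False] * 8)

        def stat(lab):
            a = make_records(times[lab], events[lab], "a")
            b = make_records(times[~lab], events[~lab], "b")
            return rc.weighted_logrank(a, b, "peto-peto").statistic

        observed = stat(labels)
        n_shuffles = 20_000
        count = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(labels)
            if stat(perm) >= observed - 1e-12:
                count += 1
        perm_p = count / n_shuffles
        chi2_p = rc.weighted_logrank(
            make_records(times[labels], events[labels], "a"),
            make_records(times[~labels], events[~labels], "b"),
            "peto-peto",
        ).p_value
        assert perm_p == pytest.approx(chi2_p, abs=0.10)

    def test_null_type_one_error_calibrated(self):
        """Both groups drawn from one exponential: rejection rate at 5%
        over 2000 trials of n = 30 + 30 lies in [0.03, 0.07]."""
        rng = np.random.default_rng(34)
        rejections = 0
        trials = 2000
        for _ in range(trials):
            ta = np.ceil(rng.exponential(300, 30))
            tb = np.ceil(rng.exponential(300, 30))
            a = make_records(np.minimum(ta, 400), ta <= 400, "a")
            b = make_records(np.minimum(tb, 400), tb <= 400, "b")
            if rc.weighted_logrank(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / trials <= 0.07

    def test_study_pattern_contrast_detected(self):
        """Hazards 4.9e-3 vs 1.0e-3 per day with n = 21 vs 45 yield a
        significant Peto-Peto contrast in the majority of replicates."""
        rng = np.random.default_rng(35)
        wins = 0
        trials = 40
        for _ in range(trials):
            ta = np.ceil(rng.exponential(1 / 4.9e-3, 21))
            tb = np.ceil(rng.exponential(1 / 1.0e-3, 45))
            a = make_records(np.minimum(ta, 365), ta <= 365, "a")
            b = make_records(np.minimum(tb, 365), tb <= 365, "b")
            if rc.weighted_logrank(a, b).p_value < 0.05:
                wins += 1
        assert wins > trials / 2
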