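import datetime as dt

import numpy as np
import pandas as pd
import pytest

import runcontingent as rc


def rng(seed=0):
    return np.random.default_rng(seed)


class TestSimulateTrack:
    def test_degenerate_parameters_give_triangle(self):
        dates, path = rc.simulate_track(
            dt.date(2017, 4, 18), 95.0, 95.0, 10.0, 0.0, 0, rng(), jitter_km_sd=0.0
        )
        peak = int(np.argmax(path))
        # apex may fall between daily samples: within one day's travel
        assert 95.0 - 10.0 <= path[peak] <= 95.0 + 1e-9
        assert (np.diff(path[: peak + 1]) >= -1e-9).all()
        assert (np.diff(path[peak:]) <= 1e-9).all()

    def test_endpoints_below_threshold_and_ceiling_respected(self):
        for seed in range(5):
            _, path = rc.simulate_track(
                dt.date(2017, 4, 22), 200.0, 150.0, 15.0, 20.0, 3, rng(seed)
            )
            assert path[0] < 43 and path[-1] < 43
            assert path.max() <= 245.0

    def test_upper_contingent_floor_between_reach_visits(self):
        _, path = rc.simulate_track(
            dt.date(2017, 4, 22), 180.0, 150.0, 15.0, 20.0, 4, rng(1)
        )
        at_reach = np.flatnonzero(path >= 179.0)
        interior = path[at_reach[0] : at_reach[-1] + 1]
        assert interior.min() >= 150.0

    def test_entry_alignment(self):
        dates, path = rc.simulate_track(
            dt.date(2017, 4, 18), 95.0, 95.0, 10.0, 5.0, 0, rng(2), jitter_km_sd=0.0
        )
        first_above = next(d for d, km in zip(dates, path) if km >= 43)
        assert first_above == dt.date(2017, 4, 18)

    def test_entry_date_monte_carlo_matches_configured_mean(self):
        cfg = rc.SyntheticConfig()
        r = rng(3)
        draws = [
            rc.synthetic._entry_date(2017, cfg.lower, r) for _ in range(1000)
        ]
        mean_ord = np.mean([d.toordinal() for d in draws])
        target = dt.date(2017, 4, 18).toordinal()
        assert abs(mean_ord - target) < 2.0


class TestEmitDetections:
    def receivers(self):
        return rc.synthetic.default_receivers(rc.SyntheticConfig())

    def track(self):
        return rc.simulate_track(
            dt.date(2017, 4, 18), 95.0, 95.0, 10.0, 10.0, 1, rng(4)
        )

    def test_probability_one_covers_every_day(self):
        dates, path = self.track()
        out = rc.emit_detections(dates, path, self.receivers(), 1.0, rng(5))
        days = pd.to_datetime(out["timestamp"]) - pd.Timedelta(hours=5)
        assert len(set(days.dt.date)) == len(dates)

    def test_probability_zero_emits_nothing(self):
        dates, path = self.track()
        out = rc.emit_detections(dates, path, self.receivers(), 0.0, rng(5))
        assert out.empty

    def test_empty_receiver_list_rejected(self):
        dates, path = self.track()
        empty = pd.DataFrame({"receiver_id": [], "river_km": [], "region": []})
        with pytest.raises(rc.ValidationError):
            rc.emit_detections(dates, path, empty, 1.0, rng(5))

    def test_detection_within_one_receiver_spacing_of_latent_position(self):
        dates, path = self.track()
        recs = self.receivers()
        out = rc.emit_detections(dates, path, recs, 1.0, rng(6), max_gap_km=5.0)
        km_of = recs.set_index("receiver_id")["river_km"]
        day = (pd.to_datetime(out["timestamp"]) - pd.Timedelta(hours=5)).dt.date
        latent = dict(zip(dates, path))
        gap = np.array([abs(km_of[r] - latent[d]) for r, d in zip(out["receiver_id"], day)])
        assert gap.max() <= 5.0 + 1e-9

    def test_observed_day_counts_bracket_field_calibration(self):
        """Mean observed days per run for 500 fish lies in [14, 34]."""
        cfg = rc.SyntheticConfig()
        recs = rc.synthetic.default_receivers(cfg)
        r = rng(7)
        counts = []
        for i in range(500):
            contingent = cfg.lower if i % 2 else cfg.upper
            target = r.uniform(*contingent.target_km_range)
            dates, path = rc.simulate_track(
                dt.date(2017, 4, 20), target, contingent.retreat_floor_km,
                15.0, 20.0, int(r.poisson(2.0)), r,
            )
            out = rc.emit_detections(dates, path, recs, cfg.daily_detection_prob, r)
            if len(out):
                day = (pd.to_datetime(out["timestamp"]) - pd.Timedelta(hours=5)).dt.date
                counts.append(len(set(day)))
        assert 14 <= np.mean(counts) <= 34


class TestSimulateMortality:
    def test_zero_hazard_censors_at_study_end(self):
        end = dt.date(2018, 12, 31)
        last, event = rc.simulate_mortality(dt.date(2017, 6, 1), 0.0, end, rng())
        assert (last, event) == (end, False)

    def test_exponential_mean_recovered(self):
        r = rng(8)
        exit_d = dt.date(2017, 6, 1)
        end = dt.date(2100, 1, 1)
        times = []
        for _ in range(10_000):
            last, event = rc.simulate_mortality(exit_d, 5e-3, end, r)
            assert event
            times.append((last - exit_d).days)
        assert np.mean(times) == pytest.approx(200.0, rel=0.03)

    def test_invalid_window_rejected(self):
        with pytest.raises(rc.ValidationError):
            rc.simulate_mortality(dt.date(2018, 6, 1), 1e-3, dt.date(2018, 5, 1), rng())


class TestSimulateEnvironment:
    def test_logistic_midpoint_temperature(self):
        cfg = rc.SyntheticConfig(temp_midpoint_month_day=(5, 1))
        env = rc.simulate_environment(2017, cfg)
        mid = env.loc[env["date"] == dt.date(2017, 5, 1), "water_temp_C"].iloc[0]
        assert mid == pytest.approx((4 + 23) / 2)

    def test_zero_scale_is_step_function(self):
        cfg = rc.SyntheticConfig(temp_scale_days=0.0)
        env = rc.simulate_environment(2017, cfg)
        before = env.loc[env["date"] == dt.date(2017, 4, 27), "water_temp_C"].iloc[0]
        after = env.loc[env["date"] == dt.date(2017, 4, 29), "water_temp_C"].iloc[0]
        assert before == pytest.approx(4.0) and after == pytest.approx(23.0)

    def test_monotone_and_positive_discharge(self):
        env = rc.simulate_environment(2017, rc.SyntheticConfig())
        assert (np.diff(env["water_temp_C"]) >= -1e-12).all()
        assert (env["discharge_m3s"] > 0).all()

    def test_shifted_midpoints_shift_lookup(self):
        a = rc.simulate_environment(2017, rc.SyntheticConfig(temp_midpoint_month_day=(4, 25)))
        b = rc.simulate_environment(2017, rc.SyntheticConfig(temp_midpoint_month_day=(4, 30)))
        ta = rc.temperature_at(a, dt.date(2017, 4, 25))
        tb = rc.temperature_at(b, dt.date(2017, 4, 30))
        assert ta == pytest.approx(tb)
        assert rc.temperature_at(b, dt.date(2017, 4, 25)) < ta


class TestSimulateCohort:
    def test_seed_reproducibility(self):
        cfg = rc.SyntheticConfig(seed=99, n_fish_lower=4, n_fish_upper=4)
        a = rc.simulate_cohort(cfg)
        b = rc.simulate_cohort(rc.SyntheticConfig(seed=99, n_fish_lower=4, n_fish_upper=4))
        pd.testing.assert_frame_equal(a.detections, b.detections)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_truth_death_after_exit(self, small_cohort):
        t = small_cohort.truth
        died = t[t["death_date"] != ""]
        exits = np.where(died["exit_y2"] != "", died["exit_y2"], died["exit_y1"])
        assert (pd.to_datetime(died["death_date"]) >= pd.to_datetime(exits)).all()

    def test_files_round_trip_through_readers(self, tmp_path, small_cohort):
        small_cohort.write(tmp_path)
        dets = rc.read_detections(tmp_path / "detections.csv")
        assert len(dets) == len(small_cohort.detections)
        rc.read_receivers(tmp_path / "receivers.csv")
        rc.read_fish(tmp_path / "fish.csv")
        rc.read_environment(tmp_path / "environment.csv")
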