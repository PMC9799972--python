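"""Linearization, tuning curves, place fields, trajectory selectivity."""

import numpy as np
import pandas as pd
import pytest

from rhythmdecode import events, spatial as SP
from rhythmdecode.session import PositionTrace, SpikeTrain


def _make_runs(n_runs=6, route="out_left", speed=40.0, fs=30.0,
               gap=5.0):
    """Constructed ideal outbound runs with known linear kinematics."""
    rows = []
    dur = SP.TRACK_LENGTH_CM / speed
    for k in range(n_runs):
        s = 10.0 + k * (dur + gap)
        t = np.arange(s, s + dur, 1 / fs)
        lin = np.clip(speed * (t - s), 0, SP.TRACK_LENGTH_CM - 1e-9)
        rows.append(dict(route=route, start=s, end=s + dur, t=t,
                         linear_cm=lin))
    return pd.DataFrame(rows)


def _field_unit(runs, center, sigma, peak_hz, base_hz=0.2, uid=0, rng=None):
    """Spikes along runs from a Gaussian rate bump plus flat background."""
    rng = rng or np.random.default_rng(0)
    spikes = []
    for r in runs.itertuples():
        dt = np.median(np.diff(r.t))
        lam = base_hz + (peak_hz - base_hz) * np.exp(
            -(r.linear_cm - center) ** 2 / (2 * sigma ** 2))
        n = rng.poisson(lam * dt)
        for tt, k in zip(r.t, n):
            spikes += list(tt + rng.uniform(0, dt, k))
    return SpikeTrain(uid, "CA1", 1, np.sort(spikes), 1.0, 0.4)


class TestLinearization:
    def test_bin_width(self):
        assert SP.LINEAR_BIN_CM == pytest.approx(1.23)

    def test_outbound_runs_classified_by_arm(self, spikes_session):
        rec, truth = spikes_session
        eps = events.run_epochs(rec.position)
        runs = SP.linearize_runs(rec.position, eps)
        assert len(runs) == len(truth.runs)
        for r in runs.itertuples():
            # match each detected run to the generator's by onset time
            k = int(np.argmin(np.abs(truth.runs["run_start"] - r.start)))
            assert abs(truth.runs["run_start"].iloc[k] - r.start) < 0.5
            assert truth.runs["route"].iloc[k] == r.route

    def test_linear_position_increases_on_ideal_run(self):
        runs = _make_runs(1)
        lin = runs.iloc[0]["linear_cm"]
        assert np.all(np.diff(lin) >= 0)
        assert lin[-1] > 120


class TestFieldStats:
    def test_uniform_rate_zero_information_unit_sparsity(self):
        sparsity, info = SP.field_stats(np.full(100, 5.0), np.full(100, 1.0))
        assert info == pytest.approx(0.0, abs=1e-12)
        assert sparsity == pytest.approx(1.0)

    def test_single_bin_field_closed_form(self):
        rate = np.zeros(100)
        rate[40] = 10.0
        sparsity, info = SP.field_stats(rate, np.full(100, 1.0))
        assert info == pytest.approx(np.log2(100))
        assert sparsity == pytest.approx(0.01)

    def test_random_curve_matches_direct_summation(self, rng):
        rate = rng.uniform(0, 10, 100)
        occ = rng.uniform(0.1, 2.0, 100)
        sparsity, info = SP.field_stats(rate, occ)
        p = occ / occ.sum()
        lbar = (p * rate).sum()
        info_oracle = sum(pi * (li / lbar) * np.log2(li / lbar)
                          for pi, li in zip(p, rate) if li > 0)
        sparsity_oracle = lbar ** 2 / (p * rate ** 2).sum()
        assert info == pytest.approx(info_oracle, rel=1e-9)
        assert sparsity == pytest.approx(sparsity_oracle, rel=1e-9)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            SP.field_stats(np.zeros(100), np.ones(100))


class TestFloodFill:
    def test_bounds_at_quarter_peak_of_constructed_bump(self):
        bins = np.arange(100) * SP.LINEAR_BIN_CM
        rate = 0.2 + 7.8 * np.exp(-(bins - 60.0) ** 2 / (2 * 6.0 ** 2))
        lo, hi = SP.flood_fill_bounds(rate, int(np.argmax(rate)))
        # analytic 25% crossing: 0.2 + 7.8 exp(-d^2/72) = 2.0
        d = 6.0 * np.sqrt(2 * np.log(7.8 / 1.8))
        expected_bins = 2 * d / SP.LINEAR_BIN_CM
        assert (hi - lo + 1) == pytest.approx(expected_bins, abs=2)
        assert lo <= np.argmax(rate) <= hi

    def test_width_monotone_in_threshold(self):
        bins = np.arange(100) * SP.LINEAR_BIN_CM
        rate = 0.2 + 7.8 * np.exp(-(bins - 60.0) ** 2 / (2 * 6.0 ** 2))
        widths = [np.diff(SP.flood_fill_bounds(rate, 49, frac=f))[0]
                  for f in (0.1, 0.25, 0.5, 0.75)]
        assert widths == sorted(widths, reverse=True)


class TestDetectPlaceField:
    def test_clear_field_detected_with_width(self, rng):
        runs = _make_runs(40)
        u = _field_unit(runs, center=60.0, sigma=6.0, peak_hz=15.0, rng=rng)
        tc = SP.linear_tuning_curve(u, runs, "out_left")
        pf = SP.detect_place_field(tc, u, runs, n_boot=100, rng=rng)
        assert pf is not None and pf.significant
        assert pf.peak_bin == pytest.approx(60.0 / SP.LINEAR_BIN_CM, abs=2)
        d = 6.0 * np.sqrt(2 * np.log(14.8 / 3.55))  # analytic 25% crossing
        assert pf.width_cm == pytest.approx(2 * d, abs=2 * SP.LINEAR_BIN_CM
                                            + 4.0)

    def test_subthreshold_peak_gives_no_field(self, rng):
        runs = _make_runs(30)
        u = _field_unit(runs, center=60.0, sigma=6.0, peak_hz=0.7, rng=rng)
        tc = SP.linear_tuning_curve(u, runs, "out_left")
        assert SP.detect_place_field(tc, u, runs, n_boot=50, rng=rng) is None

    def test_uniform_firing_rejected_by_coverage_rule(self, rng):
        runs = _make_runs(8)
        u = _field_unit(runs, center=60.0, sigma=500.0, peak_hz=5.0,
                        base_hz=5.0, rng=rng)
        tc = SP.linear_tuning_curve(u, runs, "out_left")
        pf = SP.detect_place_field(tc, u, runs, n_boot=50, rng=rng)
        assert pf is None or not pf.significant

    def test_too_few_runs_rejected(self, rng):
        runs = _make_runs(3)
        u = _field_unit(runs, 60.0, 6.0, 8.0, rng=rng)
        tc = SP.linear_tuning_curve(u, runs, "out_left")
        tc = SP.LinearTuningCurve(route=tc.route, rate_hz=tc.rate_hz,
                                  rate_raw_hz=tc.rate_raw_hz,
                                  occupancy_s=tc.occupancy_s, n_runs=3)
        with pytest.raises(ValueError):
            SP.detect_place_field(tc, u, runs, n_boot=10, rng=rng)


class TestConservation:
    def test_raw_curve_times_occupancy_recovers_spike_count(self, rng):
        runs = _make_runs(10)
        u = _field_unit(runs, 60.0, 8.0, 6.0, rng=rng)
        tc = SP.linear_tuning_curve(u, runs, "out_left")
        recovered = (tc.rate_raw_hz * tc.occupancy_s).sum()
        in_run = sum(np.sum((u.spike_times >= r.start)
                            & (u.spike_times < r.end))
                     for r in runs.itertuples())
        assert recovered == pytest.approx(in_run, rel=0.01)


class TestRateMap2D:
    def test_zero_spikes_zero_map(self, spikes_session):
        rec, _ = spikes_session
        eps = events.run_epochs(rec.position)
        silent = SpikeTrain(99, "CA1", 1, np.array([]), 0.0, 0.4)
        rm = SP.occupancy_rate_map(silent, rec.position, eps)
        assert np.nansum(rm.rate_hz) == 0.0

    def test_stationary_spikes_excluded(self, spikes_session):
        rec, _ = spikes_session
        eps = events.run_epochs(rec.position)
        tr0 = rec.trials.iloc[0]
        inside = np.linspace(tr0.port_in, tr0.port_out, 50)  # during hold
        u = SpikeTrain(99, "CA1", 1, inside, 1.0, 0.4)
        rm = SP.occupancy_rate_map(u, rec.position, eps)
        assert np.nansum(rm.rate_hz) == 0.0

    def test_homogeneous_rate_recovered(self, spikes_session, rng):
        rec, _ = spikes_session
        eps = events.run_epochs(rec.position)
        t_end = rec.position.t[-1]
        n = rng.poisson(5.0 * t_end)
        u = SpikeTrain(99, "CA1", 1, np.sort(rng.uniform(0, t_end, n)),
                       5.0, 0.4)
        rm = SP.occupancy_rate_map(u, rec.position, eps)
        visited = rm.occupancy_s > 0.5  # well-sampled bins only
        assert np.nanmean(rm.rate_hz[visited]) == pytest.approx(5.0, abs=1.0)


class TestTrajectorySelectivity:
    def _both_route_runs(self):
        left = _make_runs(8, route="out_left")
        right = _make_runs(8, route="out_right", gap=5.0)
        right["start"] += 300.0
        right["end"] += 300.0
        right["t"] = right["t"].apply(lambda a: a + 300.0)
        return pd.concat([left, right], ignore_index=True)

    def _trials_for(self, runs):
        from rhythmdecode.session import TRIAL_COLUMNS
        rows = []
        for i, r in enumerate(runs.itertuples()):
            rows.append((i, 1, r.start - 2.0, r.start - 0.6,
                         1 if r.route == "out_left" else 2, True,
                         r.end, r.end + 2.0, True))
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)

    def test_same_field_both_routes_not_selective(self, rng):
        runs = self._both_route_runs()
        u = _field_unit(runs, 60.0, 8.0, 8.0, rng=rng)
        tr = self._trials_for(runs)
        pos = PositionTrace(t=np.array([0.0, 1.0]), x=np.zeros(2),
                            y=np.zeros(2), speed=np.zeros(2))
        ts = SP.trajectory_selectivity(u, runs, tr, pos, n_shuffle=100,
                                       rng=rng)
        assert ts.corr_lr > 0.5 and not ts.selective

    def test_disjoint_fields_anticorrelated_and_selective(self, rng):
        runs = self._both_route_runs()
        left = runs[runs["route"] == "out_left"]
        right = runs[runs["route"] == "out_right"]
        ul = _field_unit(left, 35.0, 8.0, 8.0, base_hz=0.05, rng=rng)
        ur = _field_unit(right, 90.0, 8.0, 8.0, base_hz=0.05, uid=0, rng=rng)
        u = SpikeTrain(0, "CA1", 1,
                       np.sort(np.r_[ul.spike_times, ur.spike_times]),
                       1.0, 0.4)
        tr = self._trials_for(runs)
        pos = PositionTrace(t=np.array([0.0, 1.0]), x=np.zeros(2),
                            y=np.zeros(2), speed=np.zeros(2))
        ts = SP.trajectory_selectivity(u, runs, tr, pos, n_shuffle=200,
                                       rng=rng)
        assert ts.corr_lr < 0 and ts.selective

    def test_left_only_firing_gives_unit_selectivity_index(self, rng):
        runs = self._both_route_runs()
        left = runs[runs["route"] == "out_left"]
        u = _field_unit(left, 60.0, 10.0, 8.0, base_hz=0.5, rng=rng)
        tr = self._trials_for(runs)
        pos = PositionTrace(t=np.array([0.0, 1.0]), x=np.zeros(2),
                            y=np.zeros(2), speed=np.zeros(2))
        ts = SP.trajectory_selectivity(u, runs, tr, pos, n_shuffle=50,
                                       rng=rng)
        assert ts.traj_si == pytest.approx(1.0)

    def test_too_few_runs_on_a_route_rejected(self, rng):
        runs = _make_runs(8, route="out_left")
        u = _field_unit(runs, 60.0, 8.0, 8.0, rng=rng)
        with pytest.raises(ValueError):
            SP.trajectory_selectivity(u, runs, self._trials_for(runs),
                                      PositionTrace(np.array([0.0]),
                                                    np.zeros(1), np.zeros(1),
                                                    np.zeros(1)),
                                      n_shuffle=10, rng=rng)
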