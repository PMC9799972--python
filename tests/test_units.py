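"""Unit classification, responsiveness, selectivity, cross-correlograms."""

import numpy as np
import pandas as pd
import pytest

from rhythmdecode import units as U
from rhythmdecode.session import SpikeTrain


def _unit(times, rate=5.0, width=0.4, uid=0, region="CA1"):
    return SpikeTrain(unit_id=uid, region=region, tetrode_id=1,
                      spike_times=np.asarray(times, float),
                      mean_rate_hz=rate, spike_width_ms=width)


def _trials(n=20, hold=1.0, gap=4.0, odors=None, correct=None):
    odors = np.asarray(odors if odors is not None
                       else np.tile([1, 2], n // 2))
    correct = np.asarray(correct if correct is not None else [True] * n)
    rows = []
    for i in range(n):
        pin = 1.0 + i * (hold + gap)
        choice = odors[i] if correct[i] else 3 - odors[i]
        rows.append((i, int(odors[i]), pin, pin + hold, int(choice),
                     bool(correct[i]), pin + hold + 1.0, pin + hold + 2.0,
                     True))
    from rhythmdecode.session import TRIAL_COLUMNS
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


class TestClassification:
    @pytest.mark.parametrize("rate,width,expected", [
        (10.0, 0.2, "interneuron"),
        (10.0, 0.4, "pyramidal"),     # criteria are conjunctive
        (6.0, 0.2, "pyramidal"),
        (7.0, 0.2, "pyramidal"),      # strict > 7 Hz
    ])
    def test_cell_type_rule(self, rate, width, expected):
        u = _unit(np.arange(10.0), rate=rate, width=width)
        out = U.classify_units([u], [(0.0, 100.0)], _trials())
        assert out[0].cell_type == expected

    def test_active_needs_100_run_spikes(self):
        t99 = np.linspace(0.0, 9.9, 99)
        t100 = np.linspace(0.0, 9.9, 100)
        epochs = [(0.0, 10.0)]
        tr = _trials()
        assert not U.classify_units([_unit(t99)], epochs, tr)[0].active
        assert U.classify_units([_unit(t100)], epochs, tr)[0].active

    def test_odor_active_threshold_is_trial_count(self):
        tr = _trials(n=10)
        inside = tr["port_in"].to_numpy() + 0.5
        u = _unit(np.sort(inside))  # exactly one spike per odor period
        out = U.classify_units([u], [(0.0, 1.0)], tr)
        assert out[0].odor_active


class TestTaskResponsiveness:
    def test_rate_increase_detected_with_direction(self):
        tr = _trials(n=20)
        spikes = []
        for r in tr.itertuples():
            spikes += list(np.linspace(r.port_in - 1.0, r.port_in, 3,
                                       endpoint=False))   # pre: 3 Hz
            spikes += list(np.linspace(r.port_in, r.port_out, 8,
                                       endpoint=False))   # odor: 8 Hz
        resp, direction = U.task_responsiveness(_unit(np.sort(spikes)), tr)
        assert resp
        assert direction[1] == 1 and direction[2] == 1

    def test_flat_rate_not_responsive(self):
        tr = _trials(n=20)
        spikes = []
        for r in tr.itertuples():
            spikes += list(np.linspace(r.port_in - 1.0, r.port_out, 10,
                                       endpoint=False))
        resp, _ = U.task_responsiveness(_unit(np.sort(spikes)), tr)
        assert not resp


class TestChoiceSelectivity:
    def _selective_unit(self, tr, r1, r2):
        spikes = []
        for r in tr.itertuples():
            n = r1 if r.odor == 1 else r2
            if n:
                spikes += list(np.linspace(r.port_in, r.port_out, n,
                                           endpoint=False))
        return _unit(np.sort(spikes))

    def test_si_arithmetic(self, rng):
        tr = _trials(n=20)
        res = U.choice_selectivity(self._selective_unit(tr, 6, 2), tr,
                                   n_shuffle=100, rng=rng)
        assert res.si == pytest.approx(0.5)
        assert res.lambda1_hz == pytest.approx(6.0)

    def test_silent_on_one_odor_gives_si_one(self, rng):
        tr = _trials(n=20)
        res = U.choice_selectivity(self._selective_unit(tr, 10, 0), tr,
                                   n_shuffle=100, rng=rng)
        assert res.si == 1.0 and res.selective

    def test_equal_rates_give_zero(self, rng):
        tr = _trials(n=20)
        res = U.choice_selectivity(self._selective_unit(tr, 5, 5), tr,
                                   n_shuffle=100, rng=rng)
        assert res.si == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_under_label_swap(self, rng):
        tr = _trials(n=20, odors=np.r_[np.ones(10, int), 2 * np.ones(10, int)])
        u = self._selective_unit(tr, 7, 3)
        res = U.choice_selectivity(u, tr, n_shuffle=10, rng=rng)
        swapped = tr.copy()
        swapped["odor"] = 3 - swapped["odor"]
        swapped["choice"] = 3 - swapped["choice"]
        res2 = U.choice_selectivity(u, swapped, n_shuffle=10, rng=rng)
        assert res2.si == pytest.approx(-res.si)

    def test_shuffle_null_centered_for_balanced_trials(self, rng):
        tr = _trials(n=40)
        res = U.choice_selectivity(self._selective_unit(tr, 6, 2), tr,
                                   n_shuffle=2000, rng=rng)
        assert abs(res.null_mean) < 0.05

    def test_silent_unit_rejected(self, rng):
        tr = _trials(n=20)
        with pytest.raises(ValueError):
            U.choice_selectivity(_unit([]), tr, n_shuffle=10, rng=rng)


class TestSelectivityCorrelation:
    def _result(self, uid, si, si_inc):
        return U.SelectivityResult(unit_id=uid, si=si, lambda1_hz=1,
                                   lambda2_hz=1, null_mean=0, null_sd=0.01,
                                   selective=True, p_shuffle=0.01,
                                   si_incorrect=si_inc)

    def test_perfect_anticorrelation(self):
        res = [self._result(i, s, -s)
               for i, s in enumerate(np.linspace(-0.9, 0.9, 8))]
        rho, _ = U.selectivity_correlation(res)
        assert rho == pytest.approx(-1.0)

    def test_independent_sis_near_zero(self, rng):
        res = [self._result(i, a, b)
               for i, (a, b) in enumerate(rng.uniform(-1, 1, (200, 2)))]
        rho, _ = U.selectivity_correlation(res)
        assert abs(rho) < 0.2


class TestCCG:
    def test_identical_trains_peak_at_zero(self, rng):
        t = np.sort(rng.uniform(0, 60, 400))
        a = _unit(t, region="CA1")
        b = _unit(t.copy(), uid=1, region="PFC")
        res = U.jitter_corrected_ccg(a, b, [(0.0, 60.0)], n_jitter=150,
                                     rng=rng)
        assert res.significant and res.peak_lag_ms == pytest.approx(0, abs=1.3)

    def test_shifted_train_peak_sign_means_ca1_leads(self, rng):
        t = np.sort(rng.uniform(0, 60, 400))
        a = _unit(t, region="CA1")
        b = _unit(np.sort(t + 0.010), uid=1, region="PFC")
        res = U.jitter_corrected_ccg(a, b, [(0.0, 60.0)], n_jitter=150,
                                     rng=rng)
        # brute-force oracle: histogram of pairwise lags peaks at +10 ms
        lags = (b.spike_times[None, :] - a.spike_times[:, None]).ravel()
        lags = lags[np.abs(lags) <= 0.15]
        hist, edges = np.histogram(lags, np.arange(-0.15, 0.1501, 0.0025))
        oracle_peak = 1000 * (edges[np.argmax(hist)] + 0.00125)
        assert res.significant
        assert res.peak_lag_ms == pytest.approx(10.0, abs=1.3)
        assert res.peak_lag_ms == pytest.approx(oracle_peak, abs=1.3)
        np.testing.assert_array_equal(
            res.raw, hist)  # raw CCG equals the brute-force histogram

    def test_far_lag_z_values_are_standardized(self, rng):
        t1 = np.sort(rng.uniform(0, 120, 960))
        t2 = np.sort(rng.uniform(0, 120, 960))
        res = U.jitter_corrected_ccg(_unit(t1), _unit(t2, uid=1),
                                     [(0.0, 120.0)], n_jitter=400, rng=rng)
        far = np.abs(res.lags_ms) > 110
        assert 0.8 <= res.z[far].var() <= 1.25

    def test_empty_train_rejected(self, rng):
        with pytest.raises(ValueError):
            U.jitter_corrected_ccg(_unit([]), _unit([1.0], uid=1),
                                   [(0.0, 10.0)], rng=rng)
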