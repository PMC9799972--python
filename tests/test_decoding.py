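"""Rate matrices, PCA trajectory discrimination, GLM prediction, and the
Poisson Bayesian decoder."""

import numpy as np
import pandas as pd
import pytest

from rhythmdecode import decoding as D
from rhythmdecode.session import SpikeTrain, TRIAL_COLUMNS


def _trials(n=30, hold=1.0, gap=4.0):
    rows = []
    for i in range(n):
        pin = 1.0 + i * (hold + gap)
        odor = 1 + i % 2
        rows.append((i, odor, pin, pin + hold, odor, True,
                     pin + hold + 1.0, pin + hold + 2.0, True))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _poisson_unit(tr, rate, rng, uid=0):
    spikes = []
    for r in tr.itertuples():
        n = rng.poisson(rate * (r.port_out - r.port_in))
        spikes += list(rng.uniform(r.port_in, r.port_out, n))
    return SpikeTrain(uid, "CA1", 1, np.sort(spikes), rate, 0.4)


class TestRateMatrix:
    def test_silent_unit_gives_zero_column(self, rng):
        tr = _trials()
        units = [_poisson_unit(tr, 5.0, rng, uid=i) for i in range(3)]
        units.append(SpikeTrain(3, "CA1", 1, np.array([]), 0.0, 0.4))
        rm = D.build_rate_matrix(units, tr)
        assert np.all(rm.values[:, :, 3] == 0)

    def test_constant_poisson_rate_recovered(self, rng):
        tr = _trials(n=60)
        units = [_poisson_unit(tr, 10.0, rng, uid=i) for i in range(4)]
        rm = D.build_rate_matrix(units, tr)
        assert rm.values[:, :, 0].mean() == pytest.approx(10.0, abs=1.0)

    def test_too_few_units_skips_session(self, rng):
        tr = _trials()
        units = [_poisson_unit(tr, 5.0, rng, uid=i) for i in range(3)]
        with pytest.raises(D.SessionSkip):
            D.build_rate_matrix(units, tr)

    def test_bin_width_is_100ms(self, rng):
        tr = _trials()
        rm = D.build_rate_matrix(
            [_poisson_unit(tr, 5.0, rng, uid=i) for i in range(4)], tr)
        assert np.allclose(np.diff(rm.bin_edges), 0.1)


class TestPCADiscrimination:
    def _rm(self, values):
        n_tr, n_bins, n_units = values.shape
        return D.RateMatrix(values=values, unit_ids=list(range(n_units)),
                            trial_ids=np.arange(n_tr),
                            bin_edges=np.arange(0, 1.05, 0.1),
                            alignment="odor_on")

    def test_identical_class_means_no_discrimination(self, rng):
        vals = rng.poisson(5, (40, 10, 8)).astype(float)
        labels = np.r_[np.ones(20, int), np.full(20, 2)]
        td = D.pca_discrimination(self._rm(vals), labels, n_shuffle=200,
                                  rng=rng)
        assert td.discrimination_time_s is None

    def test_separation_onset_bin_detected(self, rng):
        vals = rng.poisson(5, (40, 10, 8)).astype(float)
        labels = np.r_[np.ones(20, int), np.full(20, 2)]
        vals[labels == 1, 3:, :4] += 25.0   # separable from bin 3 onward
        td = D.pca_discrimination(self._rm(vals), labels, n_shuffle=200,
                                  rng=rng)
        assert td.discrimination_time_s == pytest.approx(0.35, abs=0.05)

    def test_even_odd_control_stays_inside_band(self, rng):
        vals = rng.poisson(5, (40, 10, 8)).astype(float)
        labels = np.r_[np.ones(20, int), np.full(20, 2)]
        vals[labels == 1, :, :4] += 20.0
        td = D.pca_discrimination(self._rm(vals), labels, n_shuffle=200,
                                  rng=rng)
        assert np.all(td.evenodd_dist <= td.null_upper)
        assert np.any(td.dist > td.null_upper)


class TestGLM:
    def _data(self, rng, separable):
        tr_n = 40
        labels = np.r_[np.ones(20, int), np.full(20, 2)]
        rng.shuffle(labels)
        vals = rng.poisson(4, (tr_n, 10, 6)).astype(float)
        if separable:
            vals[labels == 1, :, :3] += 30.0
        rm = D.RateMatrix(values=vals, unit_ids=list(range(6)),
                          trial_ids=np.arange(tr_n),
                          bin_edges=np.arange(0, 1.05, 0.1),
                          alignment="odor_on")
        return rm, labels

    def test_separable_counts_decode_perfectly(self, rng):
        rm, labels = self._data(rng, separable=True)
        df = D.glm_choice_prediction(rm, labels, n_shuffle=30, rng=rng)
        assert np.all(df["accuracy"] == 1.0)
        assert df["p_perm"].iloc[-1] < 0.05

    def test_unstructured_counts_near_chance(self, rng):
        rm, labels = self._data(rng, separable=False)
        df = D.glm_choice_prediction(rm, labels, n_shuffle=50, rng=rng)
        assert df["accuracy"].iloc[-1] == pytest.approx(0.5, abs=0.2)
        assert df["p_perm"].iloc[-1] > 0.05

    def test_log_link_variant_runs(self, rng):
        rm, labels = self._data(rng, separable=True)
        df = D.glm_choice_prediction(rm, labels, n_shuffle=10, rng=rng,
                                     link="log")
        assert df["accuracy"].iloc[-1] > 0.9


class TestBayesDecoder:
    def test_closed_form_single_unit_posterior(self):
        dec = D.BayesDecoder(f=np.array([[2.0, 1.0]]), unit_ids=[0],
                             n_train=np.array([5, 5]))
        post, choice = D.bayes_decode(dec, np.array([3]), tau=1.0)
        # 8 e^-2 / (8 e^-2 + e^-1) = 8 / (8 + e)
        assert post[0] == pytest.approx(8 / (8 + np.e), rel=1e-12)
        assert choice == 1

    def test_equal_rates_give_uniform_posterior(self):
        dec = D.BayesDecoder(f=np.full((3, 2), 4.0), unit_ids=[0, 1, 2],
                             n_train=np.array([7, 5]))
        post, choice = D.bayes_decode(dec, np.array([2, 0, 5]), tau=0.5)
        assert post[0] == pytest.approx(0.5)
        assert choice == 1  # tie broken toward more training trials

    def test_log_space_matches_linear_space_oracle(self, rng):
        for _ in range(200):
            n_units = int(rng.integers(1, 6))
            dec = D.BayesDecoder(f=rng.uniform(0.01, 10, (n_units, 2)),
                                 unit_ids=list(range(n_units)),
                                 n_train=np.array([5, 5]))
            counts = rng.integers(0, 11, n_units)
            tau = float(rng.uniform(0.1, 2.0))
            post, _ = D.bayes_decode(dec, counts, tau)
            lin = D.bayes_decode_linear(dec, counts, tau)
            np.testing.assert_allclose(post, lin, atol=1e-12)
            assert post.sum() == pytest.approx(1.0)

    def test_posterior_invariant_to_rate_floor_unit(self):
        counts = np.array([[4.0, 0.0], [0.0, 3.0]])
        durs = np.array([1.0, 1.0])
        dec = D.bayes_train(counts, durs, np.array([1, 2]))
        assert dec.f[0, 1] == D.RATE_FLOOR_HZ  # silent on choice 2
        assert dec.f[1, 0] == D.RATE_FLOOR_HZ

    def test_homogeneous_training_rates_recovered(self, rng):
        counts = rng.poisson(5.0, (200, 3)).astype(float)
        durs = np.ones(200)
        labels = np.r_[np.ones(100, int), np.full(100, 2)]
        dec = D.bayes_train(counts, durs, labels)
        assert np.allclose(dec.f, 5.0, atol=0.7)

    def test_missing_choice_rejected(self):
        with pytest.raises(ValueError):
            D.bayes_train(np.ones((3, 2)), np.ones(3), np.array([1, 1, 1]))

    def test_invalid_tau_rejected(self):
        dec = D.BayesDecoder(f=np.ones((1, 2)), unit_ids=[0],
                             n_train=np.array([1, 1]))
        with pytest.raises(ValueError):
            D.bayes_decode(dec, np.array([1]), tau=0.0)


def test_quintile_geometry():
    assert D.QUINTILE_CM == pytest.approx(24.6)
    assert D.N_QUINTILES * D.QUINTILE_CM == pytest.approx(123.0)
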