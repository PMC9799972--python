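"""End-to-end validation studies on synthetic data.

Three families of checks, shared by the test suite and the acceptance
script:

* worked examples — closed-form quantities (finite-n Rayleigh p from
  printed (n, z) pairs, quintile geometry, the Poisson Bayes decoder
  against a direct linear-space evaluation);
* calibration — false-positive rates of the pipeline's five main
  significance tests on null synthetic data (nominal alpha = 0.05);
* parameter recovery and qualitative patterns — seeded synthetic
  sessions analyzed blind to their ground truth, comparing estimates
  (selectivity index, phase-locking concentration, PAC strength, place
  fields) against the generator's parameters, and checking the
  directional population-level findings the pipeline is built around.

Problem sizes are chosen so the full battery runs in minutes on one core;
see docs/methods.md for what these studies do and do not establish.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import decoding, events, pac, phaselock, rhythms, spatial, units
from .session import SpikeTrain, TRIAL_COLUMNS, odor_windows
from .synth import SynthConfig, synthesize

ALPHA = 0.05


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

def rayleigh_worked_examples() -> dict:
    """Finite-n Rayleigh p for the printed (n, z) figure examples."""
    return {
        "rayleigh_p_n242_z15p5": phaselock.rayleigh_p_from_stats(242, 15.5),
        "rayleigh_p_n99_z4p86": phaselock.rayleigh_p_from_stats(99, 4.86),
        "rayleigh_p_n870_z135p3": phaselock.rayleigh_p_from_stats(870, 135.3),
    }


def quintile_length_cm() -> float:
    return spatial.QUINTILE_CM


def bayes_oracle_study(n_cases: int = 1000, seed: int = 0) -> dict:
    """Log-space decoder vs direct linear-space evaluation.

    Random small cases (<= 5 units, <= 10 spikes per unit) plus the
    closed-form single-unit case f = (2, 1) Hz, tau = 1 s, 3 spikes,
    whose posterior for choice 1 is 8/(8 + e) ~ 0.746.
    """
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_cases):
        n_units = int(rng.integers(1, 6))
        f = rng.uniform(0.01, 10.0, (n_units, 2))
        dec = decoding.BayesDecoder(f=f, unit_ids=list(range(n_units)),
                                    n_train=np.array([10, 10]))
        counts = rng.integers(0, 11, n_units)
        tau = float(rng.uniform(0.1, 2.0))
        post, _ = decoding.bayes_decode(dec, counts, tau)
        lin = decoding.bayes_decode_linear(dec, counts, tau)
        max_diff = max(max_diff, float(np.abs(post - lin).max()))

    dec1 = decoding.BayesDecoder(f=np.array([[2.0, 1.0]]), unit_ids=[0],
                                 n_train=np.array([10, 10]))
    post1, _ = decoding.bayes_decode(dec1, np.array([3]), 1.0)
    return {"bayes_log_linear_max_abs_diff": max_diff,
            "bayes_single_unit_posterior": float(post1[0]),
            "n_cases": n_cases}


# ---------------------------------------------------------------------------
# calibration suites (false-positive rate at nominal alpha = 0.05)
# ---------------------------------------------------------------------------

def _null_trials(rng: np.random.Generator, n_trials: int = 40,
                 hold_s: float = 0.8, gap_s: float = 2.0) -> pd.DataFrame:
    """Minimal all-correct trial table with balanced odors."""
    odors = np.r_[np.ones(n_trials // 2, int), np.full(n_trials // 2, 2)]
    rng.shuffle(odors)
    rows = []
    for i in range(n_trials):
        pin = 1.0 + i * (hold_s + gap_s)
        rows.append((i, int(odors[i]), pin, pin + hold_s, int(odors[i]),
                     True, pin + hold_s + 0.5, pin + hold_s + 1.5, True))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _poisson_train_in_windows(rng, windows, rate_hz) -> np.ndarray:
    ts = []
    for s, e in windows:
        n = rng.poisson(rate_hz * (e - s))
        ts.append(rng.uniform(s, e, n))
    return np.sort(np.concatenate(ts)) if ts else np.array([])


def calibration_rayleigh(n_runs: int = 400, n_spikes: int = 100,
                         seed: int = 0) -> float:
    """Rayleigh test on uniform phases (kappa = 0)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        ph = rng.uniform(-np.pi, np.pi, n_spikes)
        _, _, p = phaselock.rayleigh_test(ph)
        hits += p < ALPHA
    return hits / n_runs


def calibration_si(n_runs: int = 250, n_shuffle: int = 200,
                   seed: int = 0) -> float:
    """Choice-selectivity permutation p on rate-matched odors."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        trials = _null_trials(rng)
        st = _poisson_train_in_windows(
            rng, list(zip(trials["port_in"], trials["port_out"])), 5.0)
        unit = SpikeTrain(unit_id=0, region="CA1", tetrode_id=1,
                          spike_times=st, mean_rate_hz=5.0,
                          spike_width_ms=0.4)
        try:
            res = units.choice_selectivity(unit, trials,
                                           n_shuffle=n_shuffle, rng=rng)
        except ValueError:
            continue
        hits += res.p_shuffle <= ALPHA
    return hits / n_runs


def calibration_pac(n_runs: int = 200, n_trials: int = 20,
                    n_shuffle: int = 200, seed: int = 0) -> float:
    """PAC trial-shuffle p with zero coupling by construction."""
    rng = np.random.default_rng(seed)
    fs = 500.0
    trial_len, gap = 1.0, 0.4
    hits = 0
    for _ in range(n_runs):
        starts = np.cumsum(rng.uniform(trial_len + 0.1,
                                       trial_len + 2 * gap, n_trials))
        t_end = starts[-1] + trial_len + 0.5
        t = np.arange(int(t_end * fs)) / fs
        raw = (0.5 * np.cos(2 * np.pi * 7.5 * t + rng.uniform(0, 2 * np.pi))
               + 0.15 * np.cos(2 * np.pi * 25 * t + rng.uniform(0, 2 * np.pi))
               + 0.3 * rng.standard_normal(t.size))
        from .session import LFPSignal
        sig = LFPSignal(region="CA1", tetrode_id=1, rate_hz=fs, samples=raw)
        phase_sig = rhythms.bandpass_zero_phase(sig, (7, 8))
        amp_sig = rhythms.bandpass_zero_phase(sig, (20, 30))
        windows = [(s, s + trial_len) for s in starts]
        res = pac.pac_null(phase_sig, amp_sig, windows,
                           n_shuffle=n_shuffle, rng=rng)
        hits += res.p <= ALPHA
    return hits / n_runs


def calibration_ccg(n_runs: int = 200, n_jitter: int = 150,
                    duration_s: float = 60.0, rate_hz: float = 8.0,
                    seed: int = 0) -> float:
    """Jitter-CCG significance on independent Poisson trains."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        a = _poisson_train_in_windows(rng, [(0, duration_s)], rate_hz)
        b = _poisson_train_in_windows(rng, [(0, duration_s)], rate_hz)
        ua = SpikeTrain(0, "CA1", 1, a, rate_hz, 0.4)
        ub = SpikeTrain(1, "PFC", 3, b, rate_hz, 0.4)
        res = units.jitter_corrected_ccg(ua, ub, [(0, duration_s)],
                                         n_jitter=n_jitter, rng=rng)
        hits += res.significant
    return hits / n_runs


def calibration_glm(n_runs: int = 200, n_trials: int = 60, n_units: int = 8,
                    n_shuffle: int = 99, seed: int = 0) -> float:
    """GLM choice prediction permutation p on label-free counts."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        vals = rng.poisson(4.0, (n_trials, 1, n_units)).astype(float) / 0.1
        rm = decoding.RateMatrix(values=vals,
                                 unit_ids=list(range(n_units)),
                                 trial_ids=np.arange(n_trials),
                                 bin_edges=np.array([0.0, 0.1]),
                                 alignment="odor_on")
        labels = np.r_[np.ones(n_trials // 2, int),
                       np.full(n_trials // 2, 2)]
        rng.shuffle(labels)
        df = decoding.glm_choice_prediction(rm, labels, n_shuffle=n_shuffle,
                                            rng=rng)
        hits += df["p_perm"].iloc[-1] <= ALPHA
    return hits / n_runs


def calibration_suite(seed: int = 0, n_runs: int = 200) -> dict:
    """All five false-positive rates at nominal alpha = 0.05."""
    return {
        "fpr_rayleigh": calibration_rayleigh(max(n_runs, 400), seed=seed),
        "fpr_si_shuffle": calibration_si(n_runs, seed=seed + 1),
        "fpr_pac": calibration_pac(n_runs, seed=seed + 2),
        "fpr_ccg": calibration_ccg(n_runs, seed=seed + 3),
        "fpr_glm": calibration_glm(n_runs, seed=seed + 4),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def _recovery_config(pac_strength: float, seed: int) -> SynthConfig:
    return SynthConfig(n_trials=80, pac_strength=pac_strength, seed=seed)


def _analyze_session_for_recovery(record, truth, rng) -> dict:
    """Estimate SI, kappa, PAC strength, and place fields blind to truth."""
    trials = record.trials
    owins = odor_windows(trials)

    band_sigs = {}
    for region, tet in (("CA1", 1), ("PFC", 3)):
        ref = [s for s in record.lfp if s.region == region
               and s.tetrode_id == tet][0]
        band_sigs[(region, "beta")] = rhythms.bandpass_zero_phase(
            ref, truth.config.beta_band)
        band_sigs[(region, "rr")] = rhythms.bandpass_zero_phase(
            ref, truth.config.rr_band)

    # kappa is a whole-session property of each unit's spike timing;
    # estimate it from all spikes for a stable MVL. Recovery is assessed
    # within band: the 20-30 Hz filter attenuates measured concentration
    # roughly twofold (phase noise between bursts) while the narrow 7-8 Hz
    # filter barely does, so pooling bands would mix attenuation regimes.
    t_end = record.lfp[0].t_end
    full = [(0.0, t_end)]
    si_true, si_est = [], []
    kap_true = {"beta": [], "rr": []}
    kap_est = {"beta": [], "rr": []}
    for u, meta in zip(record.units, truth.units.itertuples()):
        ph = phaselock.spike_phases(u, band_sigs[(u.region, meta.band)],
                                    full)
        if ph.size >= 30:
            kap_true[meta.band].append(meta.kappa)
            kap_est[meta.band].append(
                phaselock.kappa_from_mvl(phaselock.mvl(ph)))
        if meta.cell_type != "pyramidal":
            continue
        try:
            res = units.choice_selectivity(u, trials, n_shuffle=100, rng=rng)
        except ValueError:
            continue
        si_true.append(meta.si_target)
        si_est.append(res.si)

    # session PAC from the whole recording (the coupling is not confined
    # to odor periods, and the long support stabilizes the MI estimate)
    mi = pac.pac_modulation_index(band_sigs[("CA1", "rr")],
                                  band_sigs[("CA1", "beta")],
                                  [(0.0, t_end - 0.1)]).mi

    eps = events.run_epochs(record.position)
    runs = spatial.linearize_runs(record.position, eps)
    fields = []
    for u, meta in zip(record.units, truth.units.itertuples()):
        if not meta.has_field:
            continue
        if meta.field_center_cm < 30.0:
            # the choice gain persists ~0.5 s into the run by design,
            # elevating early-track rates; fields there are confounded
            # with that non-spatial signal, so geometry recovery is
            # assessed on fields clear of the run start
            continue
        try:
            tc = spatial.linear_tuning_curve(u, runs, meta.field_route)
        except ValueError:
            continue
        if tc.rate_hz.max() < 1.0:
            continue
        peak = int(np.argmax(tc.rate_hz))
        lo, hi = spatial.flood_fill_bounds(tc.rate_hz, peak)
        if lo <= 0 or hi >= spatial.N_LINEAR_BINS - 1:
            continue  # clipped by the track end: width not measurable
        fields.append(dict(center_true_bin=meta.field_center_cm
                           / spatial.LINEAR_BIN_CM,
                           center_est_bin=peak,
                           width_true_cm=meta.field_sigma_cm,
                           width_est_cm=(hi - lo + 1)
                           * spatial.LINEAR_BIN_CM))
    return dict(si_true=si_true, si_est=si_est, kappa_true=kap_true,
                kappa_est=kap_est, mi=mi, fields=fields)


def recovery_study(n_sessions: int = 20, seed: int = 0) -> dict:
    """Ground-truth recovery over seeded synthetic sessions.

    PAC strength varies across sessions (its rank correlation is across
    sessions); SI, kappa, and place-field geometry pool units across all
    sessions.
    """
    rng = np.random.default_rng(seed + 10_000)
    strengths = np.linspace(0.1, 0.9, n_sessions)
    si_t, si_e, mis, fields = [], [], [], []
    ka_t = {"beta": [], "rr": []}
    ka_e = {"beta": [], "rr": []}
    for s in range(n_sessions):
        cfg = _recovery_config(strengths[s], seed * 1000 + s)
        record, truth = synthesize(cfg, with_thermo=False)
        out = _analyze_session_for_recovery(record, truth, rng)
        si_t += out["si_true"]
        si_e += out["si_est"]
        for band in ("beta", "rr"):
            ka_t[band] += out["kappa_true"][band]
            ka_e[band] += out["kappa_est"][band]
        mis.append(out["mi"])
        fields += out["fields"]

    fdf = pd.DataFrame(fields)
    center_err = np.abs(fdf["center_est_bin"] - fdf["center_true_bin"])
    rho_kappa = {band: float(stats.spearmanr(ka_t[band], ka_e[band])[0])
                 for band in ("beta", "rr")}
    return {
        "recovery_rho_si": float(stats.spearmanr(si_t, si_e)[0]),
        "recovery_rho_kappa": min(rho_kappa.values()),
        "recovery_rho_kappa_beta": rho_kappa["beta"],
        "recovery_rho_kappa_rr": rho_kappa["rr"],
        "recovery_rho_pac": float(stats.spearmanr(strengths, mis)[0]),
        "recovery_rho_field_center": float(stats.spearmanr(
            fdf["center_true_bin"], fdf["center_est_bin"])[0]),
        "recovery_rho_field_width": float(stats.spearmanr(
            fdf["width_true_cm"], fdf["width_est_cm"])[0]),
        "recovery_field_center_median_err_bins": float(center_err.median()),
        "recovery_field_center_frac_within_2_bins": float(
            (center_err <= 2).mean()),
        "n_sessions": n_sessions,
        "n_units_si": len(si_t),
        "n_fields": len(fields),
    }


# ---------------------------------------------------------------------------
# qualitative population patterns
# ---------------------------------------------------------------------------

def pattern_si_anticorrelation(seed: int = 0) -> dict:
    """Correct vs incorrect SI across units of one choice-coding session.

    Units follow the *chosen* side, so on incorrect trials (choice is
    the other side) the odor-labelled SI flips sign, and the population
    correlation between correct- and incorrect-trial SI is negative.
    """
    record, truth = synthesize(SynthConfig(n_trials=100, seed=seed + 21),
                               with_lfp=False, with_thermo=False)
    rng = np.random.default_rng(seed + 22)
    results = []
    pyr = truth.units[truth.units["cell_type"] == "pyramidal"]["unit_id"]
    for u in record.units:
        if u.unit_id not in set(pyr):
            continue
        try:
            results.append(units.choice_selectivity(u, record.trials,
                                                    n_shuffle=200, rng=rng))
        except ValueError:
            continue
    rho, p = units.selectivity_correlation(results, selective_only=True)
    return {"si_anticorrelation_rho": rho, "si_anticorrelation_p": p,
            "n_selective_units": sum(r.selective for r in results
                                     if np.isfinite(r.si_incorrect))}


def pattern_beta_power_increase(n_sessions: int = 8, seed: int = 0) -> dict:
    """Post-odor vs pre-odor beta power contrast across sessions."""
    pre_vals, post_vals = [], []
    for s in range(n_sessions):
        cfg = SynthConfig(n_trials=20, n_pyramidal=0, n_interneuron=0,
                          ripple_rate_at_reward=0.0, seed=seed + 300 + s)
        record, truth = synthesize(cfg, with_thermo=False)
        ca1 = record.lfp_by_region("CA1")[0]
        bsig = rhythms.bandpass_zero_phase(ca1, cfg.beta_band)
        inc = record.trials[record.trials["included"]]
        pre = [(r.port_in - (r.port_out - r.port_in), r.port_in)
               for r in inc.itertuples()]
        post = [(r.port_in, r.port_out) for r in inc.itertuples()]
        pre_vals.append(rhythms.band_power_in_windows(bsig, pre))
        post_vals.append(rhythms.band_power_in_windows(bsig, post))
    res = rhythms.condition_contrast(pre_vals, post_vals, band="beta",
                                     pairing="pre_vs_post_odor")
    return {"beta_power_contrast_p": res.p,
            "beta_power_frac_sessions_increased": float(
                np.mean(res.deltas > 0)),
            "n_sessions": n_sessions}


def pattern_bayes_quintiles(seed: int = 0) -> dict:
    """Odor-trained vs quintile-trained Bayes decoding along the route.

    Session A has choice tuning that decays shortly after port exit and
    no place fields: the odor-trained decoder should beat chance only in
    the first spatial quintile. Session B gives every pyramidal cell a
    route-selective place field: quintile-trained decoding should beat
    chance everywhere.
    """
    rng = np.random.default_rng(seed + 40)
    cfg_a = SynthConfig(n_trials=100, place_frac=0.0, seed=seed + 41)
    rec_a, _ = synthesize(cfg_a, with_lfp=False, with_thermo=False)
    eps = events.run_epochs(rec_a.position)
    runs_a = spatial.linearize_runs(rec_a.position, eps)
    df_a = decoding.decode_choice_by_quintile(
        rec_a.units, rec_a.trials, runs_a, mode="odor_period",
        n_shuffle=200, rng=rng)

    cfg_b = SynthConfig(n_trials=100, place_frac=1.0, seed=seed + 42)
    rec_b, _ = synthesize(cfg_b, with_lfp=False, with_thermo=False)
    eps = events.run_epochs(rec_b.position)
    runs_b = spatial.linearize_runs(rec_b.position, eps)
    df_b = decoding.decode_choice_by_quintile(
        rec_b.units, rec_b.trials, runs_b, mode="spatial_quintile",
        n_shuffle=200, rng=rng)

    return {
        "odor_mode_accuracy": df_a["accuracy"].to_numpy(),
        "odor_mode_p": df_a["p"].to_numpy(),
        "spatial_mode_accuracy": df_b["accuracy"].to_numpy(),
        "spatial_mode_p": df_b["p"].to_numpy(),
        "odor_mode_q1_p": float(df_a["p"].iloc[0]),
        "odor_mode_q1_accuracy": float(df_a["accuracy"].iloc[0]),
        "odor_mode_q2_q5_mean_accuracy": float(
            df_a["accuracy"].iloc[1:].mean()),
        "odor_mode_q2_q5_max_accuracy": float(
            df_a["accuracy"].iloc[1:].max()),
        "spatial_mode_n_sig": int((df_b["p"] < ALPHA).sum()),
        "spatial_mode_min_accuracy": float(df_b["accuracy"].min()),
    }
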