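"""Spatial coding: occupancy-normalized rate maps, linearized tuning
curves, flood-fill place-field detection with a circular-shift bootstrap,
Skaggs information/sparsity, and trajectory selectivity.

The outbound route (odor port -> reward well) is 123 cm, linearized into
100 bins of 1.23 cm. Runs are classified by origin and destination into
``out_left`` / ``out_right``; inbound runs are dropped from tuning curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .session import PositionTrace, SpikeTrain
from .synth import STEM_CM, TRACK_LENGTH_CM

N_LINEAR_BINS = 100
LINEAR_BIN_CM = TRACK_LENGTH_CM / N_LINEAR_BINS  # 1.23 cm
N_QUINTILES = 5
QUINTILE_CM = TRACK_LENGTH_CM / N_QUINTILES      # 24.6 cm
RATE_MAP_BIN_CM = 2.0
SMOOTH_SIGMA_BINS = 2.0


@dataclass
class RateMap2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy_s: np.ndarray
    rate_hz: np.ndarray            # smoothed, masked (NaN) where unvisited
    rate_raw_hz: np.ndarray


@dataclass
class LinearTuningCurve:
    route: str
    rate_hz: np.ndarray            # length 100, smoothed
    rate_raw_hz: np.ndarray
    occupancy_s: np.ndarray
    n_runs: int


@dataclass
class PlaceField:
    route: str
    peak_bin: int
    peak_rate_hz: float
    bounds: tuple[int, int]        # inclusive bin interval
    width_cm: float
    sparsity: float
    information_bits_per_spike: float
    significant: bool


@dataclass
class TrajectorySelectivity:
    corr_lr: float
    shuffle_5pct: float
    selective: bool
    traj_si: float


def linearize_position(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Distance from the odor port along the outbound route (cm)."""
    return np.clip(y, 0.0, STEM_CM) + np.abs(np.asarray(x, float))


def linearize_runs(position: PositionTrace,
                   run_epochs: Sequence[tuple[float, float]],
                   port_xy: tuple[float, float] = (0.0, 0.0),
                   well_radius_cm: float = 12.0) -> pd.DataFrame:
    """Assign each run epoch a route and per-sample linear positions.

    A run is outbound when it starts within ``well_radius_cm`` of the
    odor port and ends near a reward well; the route (out_left /
    out_right) follows the sign of the final lateral position. Runs with
    an ambiguous origin/destination are dropped. Returns one row per
    kept run: route, start, end, and arrays of sample times / linear cm.
    """
    t, x, y = position.t, position.x, position.y
    lin = linearize_position(x, y)
    rows = []
    for s, e in run_epochs:
        m = (t >= s) & (t < e)
        if m.sum() < 3:
            continue
        xs, ys, ds = x[m], y[m], lin[m]
        start_near_port = np.hypot(xs[0] - port_xy[0], ys[0] - port_xy[1]) \
            < well_radius_cm
        ends_near_well = ds[-1] > TRACK_LENGTH_CM - well_radius_cm
        if not (start_near_port and ends_near_well):
            continue  # inbound or partial run
        route = "out_left" if xs[-1] < 0 else "out_right"
        rows.append(dict(route=route, start=float(s), end=float(e),
                         t=t[m], linear_cm=np.clip(ds, 0, TRACK_LENGTH_CM
                                                   - 1e-9)))
    return pd.DataFrame(rows)


def occupancy_rate_map(unit: SpikeTrain, position: PositionTrace,
                       run_epochs: Sequence[tuple[float, float]],
                       exclude_windows: Sequence[tuple[float, float]] = (),
                       bin_cm: float = RATE_MAP_BIN_CM) -> RateMap2D:
    """2-D occupancy-normalized rate map over run epochs.

    Spikes and occupancy are restricted to run epochs (speed filter) and
    outside the excluded windows (odor sampling, reward). The rate is
    spikes / unsmoothed occupancy per 2 cm bin, then smoothed with a
    sigma = 2 bin Gaussian; unvisited bins are NaN.
    """
    t = position.t
    dt = np.median(np.diff(t))
    mask = np.zeros(t.size, bool)
    for s, e in run_epochs:
        mask |= (t >= s) & (t < e)
    for s, e in exclude_windows:
        mask &= ~((t >= s) & (t < e))
    if not mask.any():
        raise ValueError("zero occupancy after speed/exclusion filters")

    xs, ys = position.x[mask], position.y[mask]
    x_edges = np.arange(xs.min() - bin_cm, xs.max() + 2 * bin_cm, bin_cm)
    y_edges = np.arange(ys.min() - bin_cm, ys.max() + 2 * bin_cm, bin_cm)
    occ = np.histogram2d(xs, ys, [x_edges, y_edges])[0] * dt

    st = unit.spike_times
    keep = np.zeros(st.size, bool)
    for s, e in run_epochs:
        keep |= (st >= s) & (st < e)
    for s, e in exclude_windows:
        keep &= ~((st >= s) & (st < e))
    st = st[keep]
    idx = np.clip(np.searchsorted(t, st), 1, t.size - 1)
    idx = np.where((st - t[idx - 1]) < (t[idx] - st), idx - 1, idx)
    spk = np.histogram2d(position.x[idx], position.y[idx],
                         [x_edges, y_edges])[0]

    with np.errstate(invalid="ignore", divide="ignore"):
        raw = spk / occ
    visited = occ > 0
    filled = np.where(visited, raw, 0.0)
    smooth = gaussian_filter(filled, SMOOTH_SIGMA_BINS)
    norm = gaussian_filter(visited.astype(float), SMOOTH_SIGMA_BINS)
    with np.errstate(invalid="ignore", divide="ignore"):
        smooth = np.where(norm > 1e-3, smooth / norm, np.nan)
    smooth[~visited] = np.nan
    raw[~visited] = np.nan
    return RateMap2D(x_edges=x_edges, y_edges=y_edges, occupancy_s=occ,
                     rate_hz=smooth, rate_raw_hz=raw)


def _curve_from_runs(spike_bins: np.ndarray, occ_bins: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(occ_bins > 0, spike_bins / occ_bins, 0.0)
    return raw, gaussian_filter1d(raw, SMOOTH_SIGMA_BINS, mode="nearest")


def _nearest_sample_bins(st: np.ndarray, t: np.ndarray,
                         linear_cm: np.ndarray) -> np.ndarray:
    """Spatial bin of the position sample nearest each spike time.

    Snapping spikes to sampled positions (rather than interpolating)
    keeps every spike inside an occupied bin: at 30 fps the tracker can
    skip 1.23 cm bins entirely, and an interpolated position may land in
    a bin with zero occupancy.
    """
    idx = np.searchsorted(t, st)
    idx = np.clip(idx, 1, t.size - 1)
    left_closer = (st - t[idx - 1]) < (t[idx] - st)
    idx = np.where(left_closer, idx - 1, idx)
    return np.clip((linear_cm[idx] / LINEAR_BIN_CM).astype(int), 0,
                   N_LINEAR_BINS - 1)


def _run_bin_data(unit: SpikeTrain, runs: pd.DataFrame, route: str,
                  pos_dt: float):
    """Per-run (occupancy, spike) histograms over the 100 linear bins."""
    occ_runs, spk_runs, spike_lists = [], [], []
    sel = runs[runs["route"] == route]
    for r in sel.itertuples():
        bins = np.clip((r.linear_cm / LINEAR_BIN_CM).astype(int), 0,
                       N_LINEAR_BINS - 1)
        occ = np.bincount(bins, minlength=N_LINEAR_BINS) * pos_dt
        st = unit.spike_times
        st = st[(st >= r.start) & (st < r.end)]
        sbins = _nearest_sample_bins(st, r.t, r.linear_cm)
        spk = np.bincount(sbins, minlength=N_LINEAR_BINS)
        occ_runs.append(occ)
        spk_runs.append(spk)
        spike_lists.append((st, r.start, r.end, r.t, r.linear_cm))
    return occ_runs, spk_runs, spike_lists


def linear_tuning_curve(unit: SpikeTrain, runs: pd.DataFrame, route: str,
                        pos_dt: float = 1.0 / 30.0) -> LinearTuningCurve:
    """Occupancy-normalized 100-bin tuning curve for one outbound route."""
    occ_runs, spk_runs, _ = _run_bin_data(unit, runs, route, pos_dt)
    if not occ_runs:
        raise ValueError(f"no runs on route {route!r}")
    occ = np.sum(occ_runs, axis=0)
    spk = np.sum(spk_runs, axis=0)
    raw, smooth = _curve_from_runs(spk, occ)
    return LinearTuningCurve(route=route, rate_hz=smooth, rate_raw_hz=raw,
                             occupancy_s=occ, n_runs=len(occ_runs))


def flood_fill_bounds(rate: np.ndarray, peak_bin: int,
                      frac: float = 0.25) -> tuple[int, int]:
    """Contiguous bins around the peak with rate >= frac * peak."""
    thr = frac * rate[peak_bin]
    lo = peak_bin
    while lo > 0 and rate[lo - 1] >= thr:
        lo -= 1
    hi = peak_bin
    while hi < rate.size - 1 and rate[hi + 1] >= thr:
        hi += 1
    return lo, hi


def field_stats(rate: np.ndarray, occupancy: np.ndarray
                ) -> tuple[float, float]:
    """(sparsity, Skaggs information bits/spike) of a tuning curve.

    information = sum_i p_i (l_i / l_bar) log2(l_i / l_bar),
    sparsity = (sum p_i l_i)^2 / sum p_i l_i^2, with p_i the occupancy
    probability. Raises when the mean rate is zero.
    """
    occ = np.asarray(occupancy, float)
    lam = np.asarray(rate, float)
    p = occ / occ.sum()
    lbar = float(np.sum(p * lam))
    if lbar == 0:
        raise ValueError("undefined spatial information: zero mean rate")
    ratio = lam / lbar
    info = float(np.sum(p[ratio > 0] * ratio[ratio > 0]
                        * np.log2(ratio[ratio > 0])))
    sparsity = lbar ** 2 / float(np.sum(p * lam ** 2))
    return sparsity, info


def detect_place_field(tc: LinearTuningCurve, unit: SpikeTrain,
                       runs: pd.DataFrame, n_boot: int = 500,
                       rng: Optional[np.random.Generator] = None,
                       pos_dt: float = 1.0 / 30.0) -> Optional[PlaceField]:
    """Flood-fill place field with circular-shift significance.

    A candidate needs a >= 1 Hz peak; its bounds extend from the peak to
    where the smoothed rate drops below 25% of the peak. Significance:
    the observed peak must exceed mean + 2 SD of peaks from ``n_boot``
    tuning curves in which each run's spike train is circularly shifted
    within that run (spike counts preserved exactly), and the field must
    cover less than 75% of the route.
    """
    if tc.n_runs < 5:
        raise ValueError("route traversed fewer than 5 times")
    rate = tc.rate_hz
    if not np.any(rate > 0):
        return None
    peak_bin = int(np.argmax(rate))   # argmax takes the lowest tied bin
    peak = float(rate[peak_bin])
    if peak < 1.0:
        return None
    lo, hi = flood_fill_bounds(rate, peak_bin)
    width_cm = (hi - lo + 1) * LINEAR_BIN_CM
    sparsity, info = field_stats(rate, tc.occupancy_s)

    rng = rng or np.random.default_rng()
    occ_runs, _, spike_lists = _run_bin_data(unit, runs, tc.route, pos_dt)
    occ_total = np.sum(occ_runs, axis=0)
    boot_peaks = np.empty(n_boot)
    for k in range(n_boot):
        spk = np.zeros(N_LINEAR_BINS)
        for st, s, e, rt, rl in spike_lists:
            if st.size == 0:
                continue
            dur = e - s
            shifted = np.sort(s + np.mod(st - s + rng.uniform(0, dur), dur))
            bins = _nearest_sample_bins(shifted, rt, rl)
            spk += np.bincount(bins, minlength=N_LINEAR_BINS)
        _, smooth = _curve_from_runs(spk, occ_total)
        boot_peaks[k] = smooth.max()
    significant = (peak >= boot_peaks.mean() + 2 * boot_peaks.std()
                   and width_cm < 0.75 * TRACK_LENGTH_CM)
    return PlaceField(route=tc.route, peak_bin=peak_bin, peak_rate_hz=peak,
                      bounds=(lo, hi), width_cm=width_cm, sparsity=sparsity,
                      information_bits_per_spike=info,
                      significant=bool(significant))


def run_mean_rates(unit: SpikeTrain, runs: pd.DataFrame, trials: pd.DataFrame,
                   position: PositionTrace,
                   speed_thresh: float = 3.0) -> pd.DataFrame:
    """Mean rate per run in the trajectory-SI window.

    The window opens 0.5 s after odor-port exit once speed exceeds
    3 cm/s and closes at the goal or when speed stays below 3 cm/s for
    more than 0.5 s.
    """
    port_out = trials.set_index("trial_id")["port_out"]
    rows = []
    for r in runs.itertuples():
        # match the run to its trial by containment of the run start
        tid = trials.loc[(trials["port_out"] <= r.start)
                         & (trials["reward_out"] > r.start), "trial_id"]
        if not len(tid):
            continue
        t0 = max(r.start, float(port_out[int(tid.iloc[0])]) + 0.5)
        t1 = r.end
        if t1 <= t0:
            continue
        n = np.sum((unit.spike_times >= t0) & (unit.spike_times < t1))
        rows.append(dict(route=r.route, rate_hz=n / (t1 - t0)))
    return pd.DataFrame(rows)


def trajectory_selectivity(unit: SpikeTrain, runs: pd.DataFrame,
                           trials: pd.DataFrame, position: PositionTrace,
                           n_shuffle: int = 500,
                           rng: Optional[np.random.Generator] = None,
                           pos_dt: float = 1.0 / 30.0
                           ) -> TrajectorySelectivity:
    """Left-vs-right tuning-curve anticorrelation with a route-shuffle null.

    Selective when the observed Pearson correlation of the two outbound
    tuning curves is below the 5th percentile of correlations obtained
    after permuting route identity across runs. ``traj_si`` contrasts the
    mean run rates (left - right)/(left + right).
    """
    rng = rng or np.random.default_rng()
    for route in ("out_left", "out_right"):
        if (runs["route"] == route).sum() < 5:
            raise ValueError(f"route {route!r} traversed fewer than 5 times")
    tcl = linear_tuning_curve(unit, runs, "out_left", pos_dt)
    tcr = linear_tuning_curve(unit, runs, "out_right", pos_dt)
    corr = _safe_pearson(tcl.rate_hz, tcr.rate_hz)

    labels = runs["route"].to_numpy()
    null = np.empty(n_shuffle)
    shuffled = runs.copy()
    for k in range(n_shuffle):
        shuffled["route"] = rng.permutation(labels)
        a = linear_tuning_curve(unit, shuffled, "out_left", pos_dt).rate_hz
        b = linear_tuning_curve(unit, shuffled, "out_right", pos_dt).rate_hz
        null[k] = _safe_pearson(a, b)
    pct5 = float(np.percentile(null, 5))

    rates = run_mean_rates(unit, runs, trials, position)
    rl = rates.loc[rates["route"] == "out_left", "rate_hz"].mean()
    rr_ = rates.loc[rates["route"] == "out_right", "rate_hz"].mean()
    traj_si = (rl - rr_) / (rl + rr_) if (rl + rr_) > 0 else np.nan
    return TrajectorySelectivity(corr_lr=float(corr), shuffle_5pct=pct5,
                                 selective=bool(corr < pct5),
                                 traj_si=float(traj_si))


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(stats.pearsonr(a, b)[0])
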