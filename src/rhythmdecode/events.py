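"""Behavioral events: run epochs, sharp-wave-ripple detection, SWR rates
by task period, behavioral summaries, and sniff-rate estimation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .session import LFPSignal, PositionTrace
from .rhythms import bandpass_zero_phase

RIPPLE_BAND = (150.0, 250.0)
SPEED_THRESH_CMS = 3.0


@dataclass
class SWREvent:
    tetrode_id: int
    start: float
    end: float
    peak_z: float


@dataclass
class BehaviorSummary:
    performance: float
    mean_hold_s: float
    turn_same_correct: int
    turn_opposite_correct: int
    turn_same_incorrect: int
    turn_opposite_incorrect: int
    binomial_p_correct: float
    binomial_p_incorrect: float


def run_epochs(position: PositionTrace,
               speed_thresh: float = SPEED_THRESH_CMS
               ) -> list[tuple[float, float]]:
    """Maximal contiguous intervals with running speed above threshold."""
    fast = position.speed > speed_thresh
    if not fast.any():
        return []
    edges = np.diff(fast.astype(int))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1
    if fast[0]:
        starts = np.r_[0, starts]
    if fast[-1]:
        ends = np.r_[ends, fast.size]
    t = position.t
    dt = np.median(np.diff(t)) if t.size > 1 else 0.0
    out = []
    for s, e in zip(starts, ends):
        end_t = t[e] if e < t.size else t[-1] + dt
        out.append((float(t[s]), float(end_t)))
    return out


def detect_swr(lfp_list: Sequence[LFPSignal], sd_thresh: float = 3.0,
               min_dur_s: float = 0.015, smooth_s: float = 0.004
               ) -> list[SWREvent]:
    """Sharp-wave ripples from CA1 LFP.

    Per tetrode: ripple-band (150-250 Hz) envelope from the analytic
    signal, smoothed with a 4 ms Gaussian; qualifying cores are
    contiguous runs above mean + ``sd_thresh``*SD lasting at least
    ``min_dur_s``; event boundaries extend outward to where the envelope
    falls back to the mean. Events overlapping across tetrodes are
    merged ("on at least one tetrode").
    """
    events: list[SWREvent] = []
    for sig in lfp_list:
        if sig.rate_hz < 2 * RIPPLE_BAND[1] + 100:
            raise ValueError(
                f"rate {sig.rate_hz} Hz too low for the ripple band")
        bs = bandpass_zero_phase(sig, RIPPLE_BAND)
        env = gaussian_filter1d(bs.envelope, smooth_s * sig.rate_hz)
        mu, sd = env.mean(), env.std()
        z = (env - mu) / sd
        above = z > sd_thresh
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = np.where(edges == 1)[0] + 1
        ends = np.where(edges == -1)[0] + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, above.size]
        min_n = int(np.ceil(min_dur_s * sig.rate_hz))
        below = z <= 0.0
        t = sig.times
        for s, e in zip(starts, ends):
            if e - s < min_n:
                continue
            # extend to envelope's return to the mean
            s2 = s
            while s2 > 0 and not below[s2 - 1]:
                s2 -= 1
            e2 = e
            while e2 < z.size and not below[e2]:
                e2 += 1
            events.append(SWREvent(tetrode_id=sig.tetrode_id,
                                   start=float(t[s2]),
                                   end=float(t[min(e2, z.size - 1)]),
                                   peak_z=float(z[s:e].max())))
    return _merge_events(events)


def _merge_events(events: list[SWREvent]) -> list[SWREvent]:
    if not events:
        return []
    events = sorted(events, key=lambda ev: ev.start)
    merged = [events[0]]
    for ev in events[1:]:
        last = merged[-1]
        if ev.start < last.end:
            merged[-1] = SWREvent(tetrode_id=last.tetrode_id,
                                  start=last.start,
                                  end=max(last.end, ev.end),
                                  peak_z=max(last.peak_z, ev.peak_z))
        else:
            merged.append(ev)
    return merged


def swr_rate_by_period(events: Sequence[SWREvent], trials: pd.DataFrame
                       ) -> tuple[pd.DataFrame, float]:
    """Per-trial SWR counts during odor sampling vs reward consumption.

    Returns (per-trial counts, signed-rank p for reward > odor within
    this session; p = 1 when no events occur at all).
    """
    starts = np.array([ev.start for ev in events])
    rows = []
    for tr in trials[trials["included"]].itertuples():
        odor_n = int(np.sum((starts >= tr.port_in) & (starts < tr.port_out)))
        if np.isfinite(tr.reward_in) and np.isfinite(tr.reward_out):
            rew_n = int(np.sum((starts >= tr.reward_in)
                               & (starts < tr.reward_out)))
        else:
            rew_n = 0
        rows.append((int(tr.trial_id), odor_n, rew_n))
    df = pd.DataFrame(rows, columns=["trial_id", "odor_count", "reward_count"])
    d = df["reward_count"] - df["odor_count"]
    if np.all(d == 0):
        return df, 1.0
    _, p = stats.wilcoxon(df["reward_count"], df["odor_count"])
    return df, float(p)


def behavioral_summary(trials: pd.DataFrame, position: PositionTrace,
                       turn_window_s: float = 0.5) -> BehaviorSummary:
    """Task performance, hold durations, and turn-direction concordance.

    Turn direction is the sign of the lateral (x) head displacement over
    the first 0.5 s after odor-port exit; it is concordant when it
    matches the side of the chosen reward arm (choice 1 = left =
    negative x). One-sided binomial tests ask whether concordance
    exceeds chance (0.5), separately for correct and incorrect trials.
    """
    inc = trials[trials["included"]]
    performance = float(inc["correct"].mean())
    mean_hold = float((inc["port_out"] - inc["port_in"]).mean())

    counts = {(True, True): 0, (True, False): 0,
              (False, True): 0, (False, False): 0}
    t = position.t
    for tr in inc.itertuples():
        i0 = np.searchsorted(t, tr.port_out)
        i1 = np.searchsorted(t, tr.port_out + turn_window_s)
        if i0 >= t.size or i1 >= t.size or i1 <= i0:
            continue  # position gap at port exit: skip for turn analysis
        dx = position.x[i1] - position.x[i0]
        if dx == 0:
            continue
        toward_choice = (dx < 0) == (tr.choice == 1)
        counts[(bool(tr.correct), bool(toward_choice))] += 1

    def _binom_p(same, opp):
        n = same + opp
        if n == 0:
            return 1.0
        return float(stats.binomtest(same, n, 0.5,
                                     alternative="greater").pvalue)

    sc, oc = counts[(True, True)], counts[(True, False)]
    si_, oi = counts[(False, True)], counts[(False, False)]
    return BehaviorSummary(performance=performance, mean_hold_s=mean_hold,
                           turn_same_correct=sc, turn_opposite_correct=oc,
                           turn_same_incorrect=si_, turn_opposite_incorrect=oi,
                           binomial_p_correct=_binom_p(sc, oc),
                           binomial_p_incorrect=_binom_p(si_, oi))


def sniff_rate(thermo: Optional[pd.DataFrame],
               windows: Sequence[tuple[float, float]],
               band: tuple[float, float] = (2.0, 12.0)) -> np.ndarray:
    """Peak-count sniff rate (Hz) per window from the thermocouple trace.

    The trace is bandpass filtered to the sniffing range and rate =
    number of peaks / window duration. Windows without samples yield
    NaN. Returns an array aligned with ``windows``.
    """
    if thermo is None:
        warnings.warn("no thermocouple trace: sniff rate skipped")
        return np.full(len(windows), np.nan)
    t = thermo["t"].to_numpy(float)
    v = thermo["value"].to_numpy(float)
    fs = 1.0 / np.median(np.diff(t))
    if fs < 100:
        raise ValueError("thermocouple must be sampled at >= 100 Hz")
    sos = sps.butter(3, band, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, v)
    peaks, _ = sps.find_peaks(filt)
    pk_t = t[peaks]
    out = np.empty(len(windows))
    for i, (s, e) in enumerate(windows):
        if e <= s or not np.any((t >= s) & (t < e)):
            out[i] = np.nan
            continue
        out[i] = np.sum((pk_t >= s) & (pk_t < e)) / (e - s)
    return out
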