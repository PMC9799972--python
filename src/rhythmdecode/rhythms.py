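"""Band-limited LFP analysis: zero-phase filtering, analytic signals,
multitaper spectrograms/coherograms, condition contrasts, a bootstrap
down-sampling test, and cross-region phase offsets.

Phase convention: phase 0 at the oscillation peak (the analytic signal of
cos(wt) has argument 0 at the peak), wrapped to [-pi, pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .session import LFPSignal, in_windows


@dataclass
class BandSignal:
    band: tuple
    filtered: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    envelope: np.ndarray
    rate_hz: float
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.filtered.size) / self.rate_hz


@dataclass
class TimeFreqResult:
    times: np.ndarray      # window centers, s relative to alignment event
    freqs: np.ndarray      # Hz
    values: np.ndarray     # (freqs, times) power or coherence
    zscored: bool
    alignment: str
    n_events: int


@dataclass
class ContrastResult:
    band: str
    values_a: np.ndarray
    values_b: np.ndarray
    statistic: float       # signed-rank W
    p: float

    @property
    def deltas(self) -> np.ndarray:
        return self.values_b - self.values_a


def bandpass_zero_phase(sig: LFPSignal, band: tuple[float, float],
                        order: int = 4) -> BandSignal:
    """Forward-backward (zero net phase) Butterworth bandpass + Hilbert.

    Amplitude, phase and envelope come from the analytic signal of the
    filtered trace; |analytic| serves as both amplitude and envelope.
    """
    lo, hi = band
    nyq = sig.rate_hz / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} invalid for rate {sig.rate_hz} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sig.rate_hz,
                     output="sos")
    filt = sps.sosfiltfilt(sos, np.asarray(sig.samples, float))
    # pad to a fast FFT length; the zero-padded tail is discarded
    from scipy.fft import next_fast_len
    analytic = sps.hilbert(filt, next_fast_len(filt.size))[:filt.size]
    amp = np.abs(analytic)
    phase = np.angle(analytic)
    phase = np.where(phase >= np.pi, phase - 2 * np.pi, phase)  # [-pi, pi)
    return BandSignal(band=(lo, hi), filtered=filt, amplitude=amp,
                      phase=phase, envelope=amp, rate_hz=sig.rate_hz,
                      t0=sig.t0)


# ---------------------------------------------------------------------------
# multitaper estimation (Thomson DPSS tapers)
# ---------------------------------------------------------------------------

def _taper_ffts(segments: np.ndarray, fs: float, nw: float, n_tapers: int):
    """Tapered FFTs of shape (n_seg, K, n_freq) plus the frequency grid."""
    win = segments.shape[-1]
    tapers = sps.windows.dpss(win, nw, n_tapers)      # (K, win)
    x = segments[:, None, :] * tapers[None, :, :]
    X = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    return X, freqs


def _segment_indices(n_samples: int, win: int, step: int) -> np.ndarray:
    starts = np.arange(0, n_samples - win + 1, step)
    return starts


def _event_segments(samples: np.ndarray, fs: float, t0: float,
                    events: Sequence[float], pre_s: float, post_s: float,
                    win: int, step: int):
    """Stack sliding windows around each event: (n_events, n_win, win)."""
    segs, kept = [], 0
    offsets = np.arange(0, int(round((pre_s + post_s) * fs)) - win + 1, step)
    for ev in events:
        start = int(round((ev - pre_s - t0) * fs))
        idx = start + offsets
        if idx[0] < 0 or idx[-1] + win > samples.size:
            continue
        segs.append(np.stack([samples[i:i + win] for i in idx]))
        kept += 1
    if not segs:
        raise ValueError("no alignment events fall inside the signal support")
    centers = -pre_s + (offsets + win / 2) / fs
    return np.stack(segs), centers, kept


def multitaper_spectrogram(sig: LFPSignal, alignment_events: Sequence[float],
                           window_s: float = 0.5, step_s: float = 0.05,
                           nw: float = 3.0, n_tapers: int = 5,
                           pre_s: float = 1.0, post_s: float = 2.0,
                           zscore: bool = False,
                           alignment: str = "odor_on") -> TimeFreqResult:
    """Event-aligned, trial-averaged multitaper power.

    With ``zscore`` each frequency row is standardized against the mean
    and SD of non-overlapping windows tiling the whole recording (the
    epoch baseline).
    """
    fs = sig.rate_hz
    win = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    if win < 2 * nw:
        raise ValueError("window too short for the requested time-bandwidth")
    x = np.asarray(sig.samples, float)
    segs, centers, n_ev = _event_segments(x, fs, sig.t0, alignment_events,
                                          pre_s, post_s, win, step)
    ns, nwn, _ = segs.shape
    X, freqs = _taper_ffts(segs.reshape(ns * nwn, win), fs, nw, n_tapers)
    power = (np.abs(X) ** 2).mean(axis=1).reshape(ns, nwn, -1)
    mean_power = power.mean(axis=0).T                      # (freq, time)

    if zscore:
        starts = _segment_indices(x.size, win, win)
        base = np.stack([x[i:i + win] for i in starts])
        Xb, _ = _taper_ffts(base, fs, nw, n_tapers)
        pb = (np.abs(Xb) ** 2).mean(axis=1)                # (nbase, freq)
        mu, sd = pb.mean(axis=0), pb.std(axis=0)
        sd[sd == 0] = 1.0
        mean_power = (mean_power - mu[:, None]) / sd[:, None]

    return TimeFreqResult(times=centers, freqs=freqs, values=mean_power,
                          zscored=zscore, alignment=alignment, n_events=n_ev)


def multitaper_coherogram(sig_a: LFPSignal, sig_b: LFPSignal,
                          alignment_events: Sequence[float],
                          window_s: float = 0.5, step_s: float = 0.05,
                          nw: float = 3.0, n_tapers: int = 5,
                          pre_s: float = 1.0, post_s: float = 2.0,
                          alignment: str = "odor_on") -> TimeFreqResult:
    """Trial-averaged magnitude-squared coherence.

    Cross- and auto-spectra are averaged over tapers within each
    trial-window; the coherence of each trial is then averaged across
    trials, so the bias floor for independent signals is ~1/K for K
    tapers regardless of trial count.
    """
    if sig_a.rate_hz != sig_b.rate_hz:
        raise ValueError("signals must share a sampling rate")
    if sig_a.samples.size != sig_b.samples.size:
        raise ValueError("signals must have equal length")
    fs = sig_a.rate_hz
    win = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    xa = np.asarray(sig_a.samples, float)
    xb = np.asarray(sig_b.samples, float)
    segs_a, centers, n_ev = _event_segments(xa, fs, sig_a.t0, alignment_events,
                                            pre_s, post_s, win, step)
    segs_b, _, _ = _event_segments(xb, fs, sig_b.t0, alignment_events,
                                   pre_s, post_s, win, step)
    ns, nwn, _ = segs_a.shape
    Xa, freqs = _taper_ffts(segs_a.reshape(ns * nwn, win), fs, nw, n_tapers)
    Xb, _ = _taper_ffts(segs_b.reshape(ns * nwn, win), fs, nw, n_tapers)
    sxy = (Xa * np.conj(Xb)).mean(axis=1)
    sxx = (np.abs(Xa) ** 2).mean(axis=1)
    syy = (np.abs(Xb) ** 2).mean(axis=1)
    coh = (np.abs(sxy) ** 2 / (sxx * syy)).reshape(ns, nwn, -1)
    return TimeFreqResult(times=centers, freqs=freqs,
                          values=coh.mean(axis=0).T, zscored=False,
                          alignment=alignment, n_events=n_ev)


# ---------------------------------------------------------------------------
# condition contrasts and bootstrap test
# ---------------------------------------------------------------------------

def band_power_in_windows(bsig: BandSignal,
                          windows: Sequence[tuple[float, float]]) -> float:
    """Mean analytic power (amplitude squared) over the given windows."""
    mask = in_windows(bsig.times, windows)
    if not mask.any():
        return np.nan
    return float(np.mean(bsig.amplitude[mask] ** 2))


def condition_contrast(values_a: Sequence[float], values_b: Sequence[float],
                       band: str = "beta", pairing: str = "") -> ContrastResult:
    """Wilcoxon signed-rank on within-session (B - A) differences.

    Sessions missing either condition (NaN) are dropped with a warning.
    Identical conditions give W = 0, p = 1.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.all():
        warnings.warn(f"{pairing or 'contrast'}: dropped "
                      f"{int((~ok).sum())} session(s) missing a condition")
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("need at least 2 sessions with both conditions")
    d = b - a
    if np.all(d == 0):
        return ContrastResult(band, a, b, 0.0, 1.0)
    w, p = stats.wilcoxon(b, a)
    return ContrastResult(band, a, b, float(w), float(p))


def bootstrap_downsample_test(odor_values: Sequence[float],
                              air_values: Sequence[float],
                              n_boot: int = 1000,
                              rng: Optional[np.random.Generator] = None,
                              alternative: str = "air_less"):
    """Down-sample odor trials to the air trial count, 1000 times.

    Each bootstrap resamples (with replacement) ``len(air)`` odor values
    and takes their mean. With ``alternative="air_less"`` (default) the
    one-sided p is the fraction of bootstrap means <= the observed air
    mean, testing whether the air mean sits below the odor distribution;
    ``"greater"`` counts bootstrap means >= the air mean instead.
    Returns (p, boot_means, label) where label renders a zero count as
    "< 1/n_boot".
    """
    rng = rng or np.random.default_rng()
    odor = np.asarray(odor_values, float)
    air = np.asarray(air_values, float)
    if air.size < 1 or odor.size < air.size:
        raise ValueError("need n_air >= 1 and n_odor >= n_air")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse p-value resolution")
    draws = rng.choice(odor, size=(n_boot, air.size), replace=True)
    boot = draws.mean(axis=1)
    air_mean = air.mean()
    if alternative == "air_less":
        count = int(np.sum(boot <= air_mean))
    elif alternative == "greater":
        count = int(np.sum(boot >= air_mean))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = count / n_boot
    label = f"< {1.0 / n_boot:g}" if count == 0 else f"{p:g}"
    return p, boot, label


def cross_region_phase_offset(bsig_a: BandSignal, bsig_b: BandSignal,
                              windows: Sequence[tuple[float, float]]
                              ) -> tuple[float, float]:
    """Circular mean and resultant length of per-sample phase differences.

    Returns (mean_offset_rad, resultant in [0, 1]); positive offset means
    A leads B at the band's carrier frequency.
    """
    if bsig_a.rate_hz != bsig_b.rate_hz:
        raise ValueError("signals must share a sampling rate")
    if not windows:
        raise ValueError("windows must be nonempty")
    mask = in_windows(bsig_a.times, windows)
    if not mask.any():
        raise ValueError("no samples fall inside the windows")
    dphi = bsig_a.phase[mask] - bsig_b.phase[mask]
    vec = np.exp(1j * dphi).mean()
    return float(np.angle(vec)), float(np.abs(vec))
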