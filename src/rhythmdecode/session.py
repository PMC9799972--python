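"""Session data model and bundle I/O.

A recording session couples LFP traces from up to three brain regions
(hippocampal CA1, prefrontal cortex PFC, olfactory bulb OB), sorted single
units, a trial table for the odor-cued two-choice T-maze task, an
overhead-camera position trace, and an optional nasal thermocouple signal
tracking respiration.

Conventions used throughout the package:

* all timestamps are seconds on one monotone session clock starting at 0;
* every time interval is half-open, ``[start, end)``, so an event at a
  shared boundary is never counted twice;
* all bin indices are 0-based, bin ``b`` covering ``[b*dt, (b+1)*dt)``;
* region labels come from the controlled vocabulary ``{"CA1","PFC","OB"}``.

On disk a session is a "bundle" directory::

    trials.csv        trial_id,odor,port_in,port_out,choice,correct,
                      reward_in,reward_out,included
    position.csv      t,x,y
    lfp.h5            /REGION/tetrodeNN  (attrs: rate_hz, t0)
    spikes.h5         /REGION/unitNN     (attrs: unit_id, tetrode_id,
                                          mean_rate_hz, spike_width_ms)
    thermocouple.csv  t,value            (optional)
    epochs.csv        label,start,end    (optional)
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

REGIONS = ("CA1", "PFC", "OB")

#: minimum nose-poke hold for a trial to enter any analysis (inclusive)
MIN_HOLD_S = 0.50

TRIAL_COLUMNS = [
    "trial_id", "odor", "port_in", "port_out", "choice", "correct",
    "reward_in", "reward_out", "included",
]


class SessionValidationError(ValueError):
    """An invariant of the session data model is violated."""


class BundleLoadError(IOError):
    """A bundle directory is missing a required component."""


@dataclass
class LFPSignal:
    """One continuously sampled LFP channel."""

    region: str
    tetrode_id: int
    rate_hz: float
    samples: np.ndarray
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate_hz

    @property
    def t_end(self) -> float:
        return self.t0 + self.samples.size / self.rate_hz


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit plus waveform summaries."""

    unit_id: int
    region: str
    tetrode_id: int
    spike_times: np.ndarray
    mean_rate_hz: float
    spike_width_ms: float


@dataclass
class PositionTrace:
    """Tracked 2-D head position (cm) with derived running speed (cm/s)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.speed is None:
            self.speed = derive_speed(self.t, self.x, self.y)


@dataclass
class SessionRecord:
    session_id: str
    lfp: list[LFPSignal]
    units: list[SpikeTrain]
    trials: pd.DataFrame
    position: PositionTrace
    thermocouple: Optional[pd.DataFrame] = None  # columns t, value
    epochs: list[tuple[str, float, float]] = field(default_factory=list)

    def lfp_by_region(self, region: str) -> list[LFPSignal]:
        return [s for s in self.lfp if s.region == region]

    def units_by_region(self, region: str) -> list[SpikeTrain]:
        return [u for u in self.units if u.region == region]


def derive_speed(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                 smooth_sigma_samples: float = 2.0) -> np.ndarray:
    """Speed by central differences of Gaussian-smoothed position.

    The camera trace is noisy at 30 fps; smoothing with sigma = 2 samples
    before differentiating keeps jitter from registering as movement.
    """
    if len(t) < 2:
        return np.zeros(len(t))
    xs = gaussian_filter1d(np.asarray(x, float), smooth_sigma_samples)
    ys = gaussian_filter1d(np.asarray(y, float), smooth_sigma_samples)
    vx = np.gradient(xs, t)
    vy = np.gradient(ys, t)
    return np.hypot(vx, vy)


# ---------------------------------------------------------------------------
# interval helpers (half-open convention lives here)
# ---------------------------------------------------------------------------

def in_window(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Boolean mask for t in the half-open interval [start, end)."""
    t = np.asarray(t)
    return (t >= start) & (t < end)


def in_windows(t: np.ndarray, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean mask for t falling in any of the half-open windows."""
    t = np.asarray(t)
    mask = np.zeros(t.shape, bool)
    for s, e in windows:
        mask |= (t >= s) & (t < e)
    return mask


def count_in_window(times: np.ndarray, start: float, end: float) -> int:
    """Spike count in [start, end) via binary search (times sorted)."""
    return int(np.searchsorted(times, end, "left")
               - np.searchsorted(times, start, "left"))


def windows_duration(windows: Sequence[tuple[float, float]]) -> float:
    return float(sum(e - s for s, e in windows))


def odor_windows(trials: pd.DataFrame, included_only: bool = True
                 ) -> list[tuple[float, float]]:
    """Per-trial odor-sampling windows [port_in, port_out)."""
    df = trials[trials["included"]] if included_only else trials
    return list(zip(df["port_in"].to_numpy(float), df["port_out"].to_numpy(float)))


# ---------------------------------------------------------------------------
# trial filtering
# ---------------------------------------------------------------------------

def exclude_premature_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag trials that do not enter any analysis.

    A trial is included iff the nose-poke hold lasted at least 0.50 s
    (inclusive threshold — the task demands a *minimum* of 500 ms) and a
    reward port was subsequently visited (``reward_in`` present).
    Returns a copy with the ``included`` column recomputed.
    """
    out = trials.copy()
    hold = out["port_out"] - out["port_in"]
    visited = out["reward_in"].notna()
    out["included"] = (hold >= MIN_HOLD_S) & visited
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_session(session: SessionRecord) -> None:
    """Check all data-model invariants; raise SessionValidationError."""
    for sig in session.lfp:
        if sig.region not in REGIONS:
            raise SessionValidationError(
                f"LFP region {sig.region!r} not in {REGIONS}")
        if not sig.rate_hz > 0:
            raise SessionValidationError(
                f"LFP tetrode {sig.tetrode_id}: rate_hz must be > 0")
        if not np.all(np.isfinite(sig.samples)):
            raise SessionValidationError(
                f"LFP tetrode {sig.tetrode_id}: non-finite samples")
    for u in session.units:
        if u.region not in REGIONS:
            raise SessionValidationError(
                f"unit {u.unit_id}: region {u.region!r} not in {REGIONS}")
        if np.any(np.diff(u.spike_times) < 0):
            raise SessionValidationError(
                f"unit {u.unit_id}: spike_times not nondecreasing")
        if u.mean_rate_hz < 0:
            raise SessionValidationError(
                f"unit {u.unit_id}: mean_rate_hz < 0")
        if not u.spike_width_ms > 0:
            raise SessionValidationError(
                f"unit {u.unit_id}: spike_width_ms must be > 0")

    tr = session.trials
    missing = [c for c in TRIAL_COLUMNS if c not in tr.columns]
    if missing:
        raise SessionValidationError(f"trial table missing columns {missing}")
    bad = tr[~(tr["port_out"] > tr["port_in"])]
    if len(bad):
        raise SessionValidationError(
            f"trial {int(bad.iloc[0]['trial_id'])}: port_out <= port_in")
    hold = tr["port_out"] - tr["port_in"]
    visited = tr["reward_in"].notna()
    expect_inc = (hold >= MIN_HOLD_S) & visited
    mism = tr[tr["included"].astype(bool) != expect_inc]
    if len(mism):
        raise SessionValidationError(
            f"trial {int(mism.iloc[0]['trial_id'])}: included flag "
            "inconsistent with hold/reward criterion")

    pos = session.position
    n = len(pos.t)
    if not (len(pos.x) == len(pos.y) == len(pos.speed) == n):
        raise SessionValidationError("position vectors have unequal lengths")
    if np.any(pos.speed < 0):
        raise SessionValidationError("negative speed in position trace")

    # clock consistency: spikes cannot outlive the LFP by > 1 sample
    if session.lfp and session.units:
        lfp_end = max(s.t_end for s in session.lfp)
        slack = 1.0 / min(s.rate_hz for s in session.lfp)
        for u in session.units:
            if u.spike_times.size and u.spike_times[-1] > lfp_end + slack:
                raise SessionValidationError(
                    f"unit {u.unit_id}: spike time beyond LFP support")

    starts = sorted((s, e) for _, s, e in session.epochs)
    for (s1, e1), (s2, e2) in zip(starts, starts[1:]):
        if s2 < e1:
            raise SessionValidationError("epoch intervals overlap")


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def save_session(session: SessionRecord, path: str) -> str:
    """Write a session bundle; returns the bundle directory path."""
    os.makedirs(path, exist_ok=True)

    tr = session.trials.loc[:, TRIAL_COLUMNS]
    tr.to_csv(os.path.join(path, "trials.csv"), index=False)

    pos = pd.DataFrame({"t": session.position.t, "x": session.position.x,
                        "y": session.position.y})
    pos.to_csv(os.path.join(path, "position.csv"), index=False)

    with h5py.File(os.path.join(path, "lfp.h5"), "w") as f:
        for sig in session.lfp:
            d = f.create_dataset(
                f"/{sig.region}/tetrode{sig.tetrode_id:02d}", data=sig.samples)
            d.attrs["rate_hz"] = sig.rate_hz
            d.attrs["t0"] = sig.t0

    with h5py.File(os.path.join(path, "spikes.h5"), "w") as f:
        f.attrs["session_id"] = session.session_id
        for u in session.units:
            d = f.create_dataset(
                f"/{u.region}/unit{u.unit_id:03d}", data=u.spike_times)
            d.attrs["unit_id"] = u.unit_id
            d.attrs["tetrode_id"] = u.tetrode_id
            d.attrs["mean_rate_hz"] = u.mean_rate_hz
            d.attrs["spike_width_ms"] = u.spike_width_ms

    if session.thermocouple is not None:
        session.thermocouple.to_csv(
            os.path.join(path, "thermocouple.csv"), index=False)
    if session.epochs:
        pd.DataFrame(session.epochs, columns=["label", "start", "end"]).to_csv(
            os.path.join(path, "epochs.csv"), index=False)
    return path


def load_session(path: str, session_id: Optional[str] = None) -> SessionRecord:
    """Read and validate a session bundle written by :func:`save_session`."""
    def _need(name):
        p = os.path.join(path, name)
        if not os.path.exists(p):
            raise BundleLoadError(f"bundle {path!r} is missing {name}")
        return p

    trials = pd.read_csv(_need("trials.csv"))
    trials["included"] = trials["included"].astype(bool)
    trials["correct"] = trials["correct"].astype(bool)

    posdf = pd.read_csv(_need("position.csv"))
    position = PositionTrace(t=posdf["t"].to_numpy(float),
                             x=posdf["x"].to_numpy(float),
                             y=posdf["y"].to_numpy(float))

    lfp = []
    with h5py.File(_need("lfp.h5"), "r") as f:
        for region in sorted(f.keys()):
            for name in sorted(f[region].keys()):
                d = f[region][name]
                lfp.append(LFPSignal(region=region,
                                     tetrode_id=int(name.replace("tetrode", "")),
                                     rate_hz=float(d.attrs["rate_hz"]),
                                     samples=d[()],
                                     t0=float(d.attrs["t0"])))

    units = []
    sid = session_id
    with h5py.File(_need("spikes.h5"), "r") as f:
        if sid is None:
            sid = str(f.attrs.get("session_id", os.path.basename(path)))
        for region in sorted(f.keys()):
            for name in sorted(f[region].keys()):
                d = f[region][name]
                units.append(SpikeTrain(
                    unit_id=int(d.attrs["unit_id"]),
                    region=region,
                    tetrode_id=int(d.attrs["tetrode_id"]),
                    spike_times=d[()],
                    mean_rate_hz=float(d.attrs["mean_rate_hz"]),
                    spike_width_ms=float(d.attrs["spike_width_ms"])))
    units.sort(key=lambda u: u.unit_id)

    thermo = None
    tpath = os.path.join(path, "thermocouple.csv")
    if os.path.exists(tpath):
        thermo = pd.read_csv(tpath)

    epochs = []
    epath = os.path.join(path, "epochs.csv")
    if os.path.exists(epath):
        edf = pd.read_csv(epath)
        epochs = [(str(r.label), float(r.start), float(r.end))
                  for r in edf.itertuples()]

    session = SessionRecord(session_id=sid, lfp=lfp, units=units,
                            trials=trials, position=position,
                            thermocouple=thermo, epochs=epochs)
    validate_session(session)
    return session
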