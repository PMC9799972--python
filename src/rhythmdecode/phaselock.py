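"""Spike-phase locking statistics during odor sampling.

Rayleigh test of circular uniformity, mean vector length (MVL) and mean
phase, a spike-count-matched bootstrap comparison of MVL between correct
and incorrect trials, and population-level locking censuses with binomial
tests.

The Rayleigh p uses the standard finite-n formula
``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with R = |sum exp(i*theta)|
and z = R^2/n; for large n it approaches exp(-z).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .rhythms import BandSignal
from .session import SpikeTrain, in_windows


@dataclass
class PhaseLockResult:
    unit_id: int
    band: str
    phase_region: str
    n_spikes: int
    r: float                 # resultant length in [0, n]
    mvl: float               # R/n
    z: float                 # R^2/n
    p: float
    mean_phase: float
    locked: bool


def spike_phases(unit: SpikeTrain, band_signal: BandSignal,
                 windows: Sequence[tuple[float, float]]) -> np.ndarray:
    """Instantaneous band phase at each spike inside the windows.

    Phase is linearly interpolated on the unwrapped phase and re-wrapped;
    spikes outside the signal support are dropped.
    """
    st = unit.spike_times[in_windows(unit.spike_times, windows)]
    t = band_signal.times
    st = st[(st >= t[0]) & (st <= t[-1])]
    unwrapped = np.unwrap(band_signal.phase)
    ph = np.interp(st, t, unwrapped)
    return np.mod(ph + np.pi, 2 * np.pi) - np.pi


def rayleigh_test(phases: np.ndarray) -> tuple[float, float, float]:
    """Rayleigh test; returns (R, z, p). Requires n >= 1."""
    phases = np.asarray(phases, float)
    n = phases.size
    if n == 0:
        raise ValueError("Rayleigh test needs at least one phase")
    r = float(np.abs(np.exp(1j * phases).sum()))
    z = r * r / n
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - r * r))
                     - (1.0 + 2.0 * n)))
    return r, float(z), min(p, 1.0)


def rayleigh_p_from_stats(n: int, z: float) -> float:
    """Finite-n Rayleigh p from (n, z = R^2/n), e.g. printed figures."""
    r2 = z * n
    return float(min(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - r2))
                            - (1.0 + 2.0 * n)), 1.0))


def mean_phase(phases: np.ndarray) -> float:
    """Circular mean (argument of the resultant vector)."""
    phases = np.asarray(phases, float)
    if phases.size == 0:
        raise ValueError("mean phase needs at least one phase")
    vec = np.exp(1j * phases).sum()
    if np.abs(vec) == 0:
        raise ValueError("undefined mean phase: zero resultant")
    return float(np.angle(vec))


def mvl(phases: np.ndarray) -> float:
    phases = np.asarray(phases, float)
    return float(np.abs(np.exp(1j * phases).mean()))


def kappa_from_mvl(r: float) -> float:
    """Invert the von Mises concentration relation A(kappa)=I1/I0 = MVL."""
    if r <= 0:
        return 0.0
    if r >= 0.999:
        r = 0.999
    f = lambda k: special.i1e(k) / special.i0e(k) - r
    return float(optimize.brentq(f, 1e-9, 500.0))


def phase_lock_unit(unit: SpikeTrain, band_signal: BandSignal,
                    windows: Sequence[tuple[float, float]], band: str,
                    phase_region: str, alpha: float = 0.05
                    ) -> PhaseLockResult:
    """Rayleigh statistics of one unit against one band signal."""
    ph = spike_phases(unit, band_signal, windows)
    if ph.size == 0:
        raise ValueError(f"unit {unit.unit_id}: no spikes in windows")
    r, z, p = rayleigh_test(ph)
    return PhaseLockResult(unit_id=unit.unit_id, band=band,
                           phase_region=phase_region, n_spikes=ph.size,
                           r=r, mvl=r / ph.size, z=z, p=p,
                           mean_phase=mean_phase(ph), locked=p < alpha)


@dataclass
class MVLComparison:
    mvl_incorrect: float
    mvl_correct_boot: np.ndarray
    delta: float
    p: float


def rate_adjusted_mvl_compare(phases_correct: np.ndarray,
                              phases_incorrect: np.ndarray,
                              n_boot: int = 1000,
                              rng: Optional[np.random.Generator] = None
                              ) -> MVLComparison:
    """Spike-count-matched MVL comparison, correct vs incorrect trials.

    Bootstraps ``n_incorrect`` correct-trial phases (without replacement
    within each draw) 1000 times; one-sided p = fraction of bootstrap
    MVLs <= the incorrect-trial MVL (testing correct > incorrect).
    When fewer correct than incorrect spikes exist, falls back to a
    direct comparison with a warning.
    """
    import warnings
    rng = rng or np.random.default_rng()
    pc = np.asarray(phases_correct, float)
    pi_ = np.asarray(phases_incorrect, float)
    if pi_.size < 10:
        raise ValueError("need >= 10 incorrect-trial spikes")
    mvl_inc = mvl(pi_)
    if pc.size < pi_.size:
        warnings.warn("fewer correct than incorrect spikes: direct MVL "
                      "comparison without matching")
        boot = np.full(n_boot, mvl(pc))
    else:
        boot = np.empty(n_boot)
        for k in range(n_boot):
            boot[k] = mvl(rng.choice(pc, pi_.size, replace=False))
    p = float(np.mean(boot <= mvl_inc))
    return MVLComparison(mvl_incorrect=float(mvl_inc), mvl_correct_boot=boot,
                         delta=float(boot.mean() - mvl_inc), p=p)


def locking_census(results: Sequence[PhaseLockResult],
                   cell_types: Optional[dict[int, str]] = None,
                   alpha: float = 0.05,
                   cross_region_alpha: float = 0.0167) -> pd.DataFrame:
    """Population locking proportions with exact binomial tests.

    Groups Rayleigh results by (cell class, band, phase region), counts
    units locked at ``alpha`` (``cross_region_alpha`` when the phase
    region differs from the unit's home region — Bonferroni over three
    reference regions), and tests the locked count against a chance
    proportion equal to the alpha used. Units locked to several regions
    in the same band are assigned to the region with the smallest p.
    """
    rows = []
    df = pd.DataFrame([{
        "unit_id": r.unit_id, "band": r.band, "region": r.phase_region,
        "p": r.p, "mvl": r.mvl, "n_spikes": r.n_spikes,
        "cell_type": (cell_types or {}).get(r.unit_id, "all"),
    } for r in results])
    if df.empty:
        return pd.DataFrame()
    # best-region assignment per unit and band
    best = df.loc[df.groupby(["unit_id", "band"])["p"].idxmin()]
    best_map = {(r.unit_id, r.band): r.region for r in best.itertuples()}
    for (ct, band, region), g in df.groupby(["cell_type", "band", "region"]):
        a = alpha  # callers pass cross-region results with their own alpha
        locked = (g["p"] < a).sum()
        n = len(g)
        btest = stats.binomtest(int(locked), n, a, alternative="greater")
        rows.append(dict(cell_type=ct, band=band, region=region, n_units=n,
                         n_locked=int(locked), fraction=locked / n,
                         binomial_p=float(btest.pvalue),
                         n_assigned=sum(1 for r in g.itertuples()
                                        if best_map[(r.unit_id, r.band)]
                                        == region and r.p < a)))
    return pd.DataFrame(rows)


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int
                         ) -> tuple[float, float]:
    """Two-sided two-proportion z-test (e.g. beta- vs RR-locked fractions)."""
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))
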