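"""Synthetic session generator with recorded ground truth.

Builds :class:`~rhythmdecode.session.SessionRecord` objects carrying the
statistical structure the analysis pipeline assumes, with every generative
parameter recorded so that recovery tests can compare estimates against
truth:

* LFP per region = respiratory-rhythm (RR) carrier + a beta (20-30 Hz)
  burst process whose burst amplitudes are coupled to RR phase
  (phase-amplitude coupling of tunable strength) and boosted during
  odor sampling, + 1/f (pink) background noise; CA1 channels
  additionally receive a shared train of ripple-band (150-250 Hz)
  bursts during reward consumption.
* Units are inhomogeneous Poisson processes whose intensity multiplies a
  baseline by (i) a choice gain active from odor onset until shortly
  after port exit, scaled so the realized selectivity index equals its
  target, (ii) a von Mises spike-timing gain locked to a rhythm phase
  (normalized to leave the mean rate unchanged), and (iii) a spatial
  Gaussian field on the linearized outbound route, active only on the
  unit's preferred trajectory.
* Behavior follows the odor-cued T-maze: hold at the odor port
  (>= 0.5 s), turn toward the chosen arm, run the 123 cm outbound route
  at constant speed, consume reward, run back.

Sampling is by thinning (accept/reject under a bound on the intensity),
so the Poisson process is exact. The same phase processes drive both the
LFP synthesis and the spike-timing gains — beta units lock to the phase
of the burst process the LFP actually carries — which is what couples
spikes to the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import i0

from .session import (LFPSignal, PositionTrace, SessionRecord, SpikeTrain,
                      TRIAL_COLUMNS)

TRACK_LENGTH_CM = 123.0  # linearized outbound route (stem + reward arm)
STEM_CM = 80.0
ARM_CM = 43.0


@dataclass
class SynthConfig:
    """Generative parameters; defaults are the study conditions.

    Trial counts and behavioral statistics follow the task as run
    (about 100-150 trials per day, 77% correct, 0.82 s mean odor
    sampling); rhythm parameters sit at the band centers (RR 7.5 Hz,
    beta carrier 25 Hz). Effect sizes without a published value
    (odor beta gain, PAC strength, choice/place gains) are set so that
    every pipeline contrast is detectable in a single ~100-trial
    session; they are synthetic choices, not measured quantities.
    """

    n_trials: int = 100
    p_correct: float = 0.77
    hold_mean_s: float = 0.82
    hold_sd_s: float = 0.15

    # rhythms
    rr_hz: float = 7.5
    beta_hz: float = 25.0
    beta_band: tuple = (20.0, 30.0)
    rr_band: tuple = (7.0, 8.0)
    pac_strength: float = 0.5        # fraction of burst amplitude on RR phase
    odor_beta_gain: float = 2.0      # beta *power* multiplier during odor
    a_rr: float = 0.5
    beta_base_amp: float = 0.12      # continuous carrier keeping phase defined
    beta_burst_rate_hz: float = 4.0
    beta_burst_sigma_s: float = 0.015
    beta_burst_amp: float = 1.5
    noise_exponent: float = 1.0
    noise_scale: float = 0.5

    # ripples
    ripple_rate_at_reward: float = 0.5   # Hz within reward windows
    ripple_hz: float = 200.0
    ripple_dur_s: tuple = (0.05, 0.08)
    ripple_amp: float = 0.8

    # units (per region, CA1 and PFC)
    n_pyramidal: int = 12
    n_interneuron: int = 3
    si_range: tuple = (-0.85, 0.85)      # targets tile this range
    kappa_range: tuple = (0.3, 3.0)
    pyr_base_hz: tuple = (3.0, 8.0)
    int_base_hz: tuple = (15.0, 25.0)
    pyr_width_ms: tuple = (0.35, 0.60)
    int_width_ms: tuple = (0.15, 0.28)
    odor_rate_gain: float = 1.6          # rate boost during odor sampling
    choice_persist_s: float = 1.0        # choice gain outlives port exit
    place_frac: float = 0.75             # fraction of pyr cells with a field
    place_amp: float = 6.0               # peak gain above baseline
    place_sigma_cm: tuple = (4.0, 10.0)
    place_margin_cm: float = 12.0        # keep centers off the route ends

    # behavior / kinematics
    run_speed_cms: float = 40.0
    pre_wait_s: float = 2.0
    turn_s: float = 0.5
    reward_mean_s: float = 2.5
    reward_sd_s: float = 0.3

    # sampling rates
    lfp_rate_hz: float = 1500.0
    pos_rate_hz: float = 30.0
    thermo_rate_hz: float = 200.0

    # respiration (thermocouple)
    sniff_pre_hz: float = 6.2
    sniff_odor_hz: float = 7.1

    regions_lfp: tuple = ("CA1", "PFC", "OB")
    n_ca1_tetrodes: int = 2
    seed: int = 0


@dataclass
class GroundTruth:
    """Generative parameters aligned 1:1 with the emitted session."""

    units: pd.DataFrame          # per-unit targets (SI, kappa, mu, field, ...)
    runs: pd.DataFrame           # trial_id, route, run_start, run_end
    pac_strength: float
    config: SynthConfig
    phases: dict = field(default_factory=dict)


# region-specific deterministic phase offsets (rad) added to the shared
# session carriers; OB leads, consistent with a respiratory drive
_REGION_OFFSET = {"OB": 0.0, "CA1": 0.5, "PFC": 0.9}


def _hold_times(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    h = rng.normal(cfg.hold_mean_s, cfg.hold_sd_s, n)
    # the task aborts holds under 0.5 s; resample rather than clip so the
    # distribution has no atom at the threshold
    while np.any(h < 0.5):
        bad = h < 0.5
        h[bad] = rng.normal(cfg.hold_mean_s, cfg.hold_sd_s, bad.sum())
    return h


def gen_trials(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trial table with the full event schedule on the session clock.

    Odors are balanced to within one trial and shuffled (pseudo-random
    order); the choice matches the odor-assigned side with probability
    ``p_correct``. Odor 1 sends the animal to the left arm, odor 2 to
    the right.
    """
    n = int(cfg.n_trials)
    if n < 1:
        raise ValueError("n_trials must be >= 1")
    odors = np.r_[np.ones(n // 2 + n % 2, int), np.full(n // 2, 2)]
    rng.shuffle(odors)
    correct = rng.random(n) < cfg.p_correct
    choice = np.where(correct, odors, 3 - odors)

    holds = _hold_times(cfg, rng, n)
    reward_dur = np.maximum(0.8, rng.normal(cfg.reward_mean_s, cfg.reward_sd_s, n))
    run_dur = TRACK_LENGTH_CM / cfg.run_speed_cms

    rows = []
    t = 1.0
    for i in range(n):
        port_in = t + cfg.pre_wait_s + rng.uniform(0.0, 0.4)
        port_out = port_in + holds[i]
        reward_in = port_out + cfg.turn_s + run_dur
        reward_out = reward_in + reward_dur[i]
        rows.append((i, int(odors[i]), port_in, port_out, int(choice[i]),
                     bool(correct[i]), reward_in, reward_out, True))
        t = reward_out + run_dur  # inbound run back to the port
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _route_xy(d: np.ndarray, side: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linearized distance d (cm) to T-maze coordinates.

    Stem runs from (0,0) to (0,STEM_CM); arms extend laterally, left for
    side 1 (negative x), right for side 2.
    """
    d = np.asarray(d, float)
    y = np.minimum(d, STEM_CM)
    lateral = np.maximum(d - STEM_CM, 0.0)
    sign = -1.0 if side == 1 else 1.0
    return sign * lateral, y


def gen_position(cfg: SynthConfig, trials: pd.DataFrame,
                 rng: np.random.Generator
                 ) -> tuple[PositionTrace, pd.DataFrame]:
    """Position trace following the trial schedule; returns (trace, runs).

    ``runs`` lists the outbound run of every trial (trial_id, route,
    run_start, run_end) — the generator's ground truth for run-epoch and
    linearization code.
    """
    t_end = session_end_time(cfg, trials)
    t = np.arange(0.0, t_end, 1.0 / cfg.pos_rate_hz)
    x = np.zeros_like(t)
    y = np.zeros_like(t)

    run_dur = TRACK_LENGTH_CM / cfg.run_speed_cms
    runs = []
    for tr in trials.itertuples():
        side = int(tr.choice)
        sign = -1.0 if side == 1 else 1.0
        run_start = tr.port_out + cfg.turn_s
        # turn: small lateral displacement toward the chosen arm, slow
        m = (t >= tr.port_out) & (t < run_start)
        frac = (t[m] - tr.port_out) / cfg.turn_s
        x[m] = sign * 1.2 * frac
        # outbound run
        m = (t >= run_start) & (t < tr.reward_in)
        d = cfg.run_speed_cms * (t[m] - run_start)
        xr, yr = _route_xy(d, side)
        taper = np.clip(1.0 - d / STEM_CM, 0.0, 1.0)
        x[m] = xr + sign * 1.2 * taper
        y[m] = yr
        # reward consumption at the well
        m = (t >= tr.reward_in) & (t < tr.reward_out)
        xw, yw = _route_xy(np.array([TRACK_LENGTH_CM]), side)
        x[m], y[m] = xw[0], yw[0]
        # inbound run
        ret_end = tr.reward_out + run_dur
        m = (t >= tr.reward_out) & (t < ret_end)
        d = TRACK_LENGTH_CM - cfg.run_speed_cms * (t[m] - tr.reward_out)
        xr, yr = _route_xy(d, side)
        x[m], y[m] = xr, yr
        runs.append((int(tr.trial_id),
                     "out_left" if side == 1 else "out_right",
                     run_start, float(tr.reward_in)))

    # camera jitter; small enough that smoothed speed stays under 3 cm/s
    x += rng.normal(0.0, 0.03, t.size)
    y += rng.normal(0.0, 0.03, t.size)
    runs_df = pd.DataFrame(runs, columns=["trial_id", "route",
                                          "run_start", "run_end"])
    return PositionTrace(t=t, x=x, y=y), runs_df


def session_end_time(cfg: SynthConfig, trials: pd.DataFrame) -> float:
    return float(trials["reward_out"].iloc[-1]
                 + TRACK_LENGTH_CM / cfg.run_speed_cms + 1.0)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f**exponent power spectrum."""
    from scipy.fft import next_fast_len
    nfft = next_fast_len(n)
    white = rng.standard_normal(nfft)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(nfft)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * shape, nfft)[:n]
    sd = out.std()
    return out / sd if sd > 0 else out


def _odor_amp_profile(t: np.ndarray, trials: pd.DataFrame, gain: float
                      ) -> np.ndarray:
    """Amplitude multiplier sqrt(gain) inside odor windows (power x gain)."""
    prof = np.ones_like(t)
    g = np.sqrt(gain)
    idx_in = np.searchsorted(t, trials["port_in"].to_numpy())
    idx_out = np.searchsorted(t, trials["port_out"].to_numpy())
    for a, b in zip(idx_in, idx_out):
        prof[a:b] = g
    return prof


def gen_beta_process(cfg: SynthConfig, rng: np.random.Generator,
                     phases: dict, t_end: float) -> np.ndarray:
    """Complex beta-band process: base carrier + incoherent bursts.

    Each burst is a Gaussian-windowed 25 Hz wavelet with an independent
    carrier phase and an amplitude scaled by 1 + pac_strength *
    cos(RR phase at burst time). Incoherent burst phases keep the
    phase-amplitude coupling in the broadband power envelope (where the
    20-30 Hz analysis filter can see it) instead of concentrating it in
    sidebands at carrier +/- RR frequency, which that filter removes.
    The argument of the returned process is the generative beta phase
    that spike timing locks to; its real part enters the LFP.
    """
    fs = cfg.lfp_rate_hz
    n = int(np.ceil(t_end * fs))
    t = np.arange(n) / fs
    z = cfg.beta_base_amp * np.exp(
        1j * (2 * np.pi * cfg.beta_hz * t + phases["beta0"]))

    n_bursts = rng.poisson(cfg.beta_burst_rate_hz * t_end)
    burst_t = np.sort(rng.uniform(0.0, t_end, n_bursts))
    xi = rng.uniform(0.0, 2 * np.pi, n_bursts)
    amps = cfg.beta_burst_amp * (1.0 + cfg.pac_strength * np.cos(
        2 * np.pi * cfg.rr_hz * burst_t + phases["rr0"]))

    sig_b = cfg.beta_burst_sigma_s
    half = int(round(3 * sig_b * fs))
    kern_t = np.arange(-half, half + 1) / fs
    kern = np.exp(-kern_t ** 2 / (2 * sig_b ** 2))
    idx = np.round(burst_t * fs).astype(int)
    for k, i in enumerate(idx):
        a, b = max(0, i - half), min(n, i + half + 1)
        tt = (np.arange(a, b) - i) / fs
        z[a:b] += (amps[k] * kern[a - (i - half):kern.size
                                  - ((i + half + 1) - b)]
                   * np.exp(1j * (2 * np.pi * cfg.beta_hz * tt + xi[k])))
    return z


def gen_lfp(cfg: SynthConfig, trials: pd.DataFrame,
            rng: np.random.Generator, phases: Optional[dict] = None,
            beta_z: Optional[np.ndarray] = None) -> list[LFPSignal]:
    """LFP channels for all regions (two CA1 tetrodes by default)."""
    if phases is None:
        phases = draw_session_phases(rng)
    t_end = session_end_time(cfg, trials)
    fs = cfg.lfp_rate_hz
    n = int(np.ceil(t_end * fs))
    t = np.arange(n) / fs

    odor_prof = _odor_amp_profile(t, trials, cfg.odor_beta_gain)

    if beta_z is None:
        beta_z = gen_beta_process(cfg, rng, phases, t_end)

    signals = []
    tet = 1
    for region in cfg.regions_lfp:
        n_chan = cfg.n_ca1_tetrodes if region == "CA1" else 1
        off = _REGION_OFFSET.get(region, 0.0)
        phi_rr = 2 * np.pi * cfg.rr_hz * t + phases["rr0"] + off
        beta_part = np.real(beta_z * np.exp(1j * off)) * odor_prof
        base = cfg.a_rr * np.cos(phi_rr) + beta_part
        if region == "CA1":
            # one population event train shared by all CA1 tetrodes
            ripples = _draw_ripples(trials, cfg, rng)
        for _ in range(n_chan):
            sig = base + cfg.noise_scale * _pink_noise(n, cfg.noise_exponent, rng)
            if region == "CA1":
                _inject_ripples(sig, t, fs, cfg, ripples)
            signals.append(LFPSignal(region=region, tetrode_id=tet,
                                     rate_hz=fs, samples=sig))
            tet += 1
    return signals


def _draw_ripples(trials: pd.DataFrame, cfg: SynthConfig,
                  rng: np.random.Generator) -> list[tuple[float, float]]:
    """Poisson ripple (time, duration) pairs inside reward windows."""
    out = []
    if cfg.ripple_rate_at_reward <= 0:
        return out
    for tr in trials.itertuples():
        dur_win = tr.reward_out - tr.reward_in
        k = rng.poisson(cfg.ripple_rate_at_reward * dur_win)
        for _ in range(k):
            out.append((rng.uniform(tr.reward_in + 0.05,
                                    tr.reward_out - 0.05),
                        rng.uniform(*cfg.ripple_dur_s)))
    return out


def _inject_ripples(sig: np.ndarray, t: np.ndarray, fs: float,
                    cfg: SynthConfig,
                    ripples: list[tuple[float, float]]) -> None:
    """Add Gaussian-windowed ripple-band bursts at the given times."""
    for t0, dur in ripples:
        half = dur / 2
        i0_, i1_ = np.searchsorted(t, [t0 - half, t0 + half])
        tt = t[i0_:i1_] - t0
        env = np.exp(-tt ** 2 / (2 * (dur / 6) ** 2))
        sig[i0_:i1_] += cfg.ripple_amp * env * np.cos(
            2 * np.pi * cfg.ripple_hz * tt)


def draw_session_phases(rng: np.random.Generator) -> dict:
    return {"rr0": rng.uniform(0, 2 * np.pi),
            "beta0": rng.uniform(0, 2 * np.pi)}


def _unit_roster(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-unit generative parameters for CA1 and PFC."""
    rows = []
    uid = 0
    for region in ("CA1", "PFC"):
        npyr, nint = cfg.n_pyramidal, cfg.n_interneuron
        si = np.linspace(*cfg.si_range, npyr)
        rng.shuffle(si)
        kap = rng.uniform(*cfg.kappa_range, npyr + nint)
        n_place = int(round(cfg.place_frac * npyr))
        place_ids = rng.choice(npyr, n_place, replace=False)
        lo = cfg.place_margin_cm
        hi = TRACK_LENGTH_CM - cfg.place_margin_cm
        centers = np.linspace(lo, hi, n_place)
        rng.shuffle(centers)
        for j in range(npyr + nint):
            is_int = j >= npyr
            if is_int:
                base = rng.uniform(*cfg.int_base_hz)
                width = rng.uniform(*cfg.int_width_ms)
                si_j, band = 0.0, "beta"
                # interneurons sit in the upper half of the locking range
                lo_k, hi_k = cfg.kappa_range
                kappa = rng.uniform((lo_k + hi_k) / 2, hi_k)
                has_field, center, sigma, route = False, np.nan, np.nan, ""
            else:
                base = rng.uniform(*cfg.pyr_base_hz)
                width = rng.uniform(*cfg.pyr_width_ms)
                si_j = si[j]
                band = "beta" if j % 2 == 0 else "rr"
                kappa = kap[j]
                has_field = j in place_ids
                if has_field:
                    k = int(np.where(place_ids == j)[0][0])
                    center = centers[k]
                    sigma = rng.uniform(*cfg.place_sigma_cm)
                    route = "out_left" if rng.random() < 0.5 else "out_right"
                else:
                    center, sigma, route = np.nan, np.nan, ""
            rows.append(dict(unit_id=uid, region=region,
                             cell_type="interneuron" if is_int else "pyramidal",
                             tetrode_id=1 if region == "CA1" else 3,
                             baseline_hz=base, width_ms=width,
                             si_target=si_j, band=band, kappa=kappa,
                             mu=rng.uniform(-np.pi, np.pi),
                             has_field=has_field, field_center_cm=center,
                             field_sigma_cm=sigma, field_route=route))
            uid += 1
    return pd.DataFrame(rows)


def gen_spikes(cfg: SynthConfig, trials: pd.DataFrame, runs: pd.DataFrame,
               rng: np.random.Generator, phases: Optional[dict] = None,
               roster: Optional[pd.DataFrame] = None,
               beta_z: Optional[np.ndarray] = None
               ) -> tuple[list[SpikeTrain], pd.DataFrame]:
    """Inhomogeneous-Poisson spike trains by exact thinning.

    Intensity: lambda(t) = baseline * choice/odor gain * von Mises gain
    * place gain. The von Mises gain exp(kappa*cos(theta-mu))/I0(kappa)
    has unit mean over phase, so kappa shapes spike timing without
    changing the rate.
    """
    if phases is None:
        phases = draw_session_phases(rng)
    if roster is None:
        roster = _unit_roster(cfg, rng)
    t_end = session_end_time(cfg, trials)

    port_in = trials["port_in"].to_numpy()
    port_out = trials["port_out"].to_numpy()
    choice = trials["choice"].to_numpy()
    run_start = runs["run_start"].to_numpy()
    run_end = runs["run_end"].to_numpy()
    run_side = np.where(runs["route"].to_numpy() == "out_left", 1, 2)

    units = []
    for row in roster.itertuples():
        base = row.baseline_hz
        kappa, mu = row.kappa, row.mu
        vm_max = np.exp(kappa) / i0(kappa)
        gain_choice_max = cfg.odor_rate_gain * (1.0 + abs(row.si_target))
        gain_place_max = (1.0 + cfg.place_amp) if row.has_field else 1.0
        lam_max = base * gain_choice_max * vm_max * gain_place_max

        n_cand = rng.poisson(lam_max * t_end)
        tc = np.sort(rng.uniform(0.0, t_end, n_cand))

        off = _REGION_OFFSET.get(row.region, 0.0)
        if row.band == "beta" and beta_z is not None:
            # lock to the burst process's own phase (what the LFP carries)
            grid = np.arange(beta_z.size) / cfg.lfp_rate_hz
            zr = np.interp(tc, grid, beta_z.real)
            zi = np.interp(tc, grid, beta_z.imag)
            theta = np.angle(zr + 1j * zi) + off
        else:
            f_band = cfg.beta_hz if row.band == "beta" else cfg.rr_hz
            ph0 = phases["beta0"] if row.band == "beta" else phases["rr0"]
            theta = 2 * np.pi * f_band * tc + ph0 + off
        lam = np.full(tc.shape, base) * (np.exp(kappa * np.cos(theta - mu))
                                         / i0(kappa))

        # choice/odor gain between odor onset and shortly after port exit
        idx = np.searchsorted(port_in, tc, "right") - 1
        idx = np.clip(idx, 0, len(port_in) - 1)
        t_rel_ok = tc >= port_in[idx]
        in_odor = t_rel_ok & (tc < port_out[idx])
        in_persist = t_rel_ok & (tc >= port_out[idx]) & (
            tc < port_out[idx] + cfg.choice_persist_s)
        cg = np.where(choice[idx] == 1, 1.0 + row.si_target,
                      1.0 - row.si_target)
        lam = lam * np.where(in_odor, cfg.odor_rate_gain * cg,
                             np.where(in_persist, cg, 1.0))

        # place gain on the preferred outbound route
        if row.has_field:
            ridx = np.searchsorted(run_start, tc, "right") - 1
            ridx = np.clip(ridx, 0, len(run_start) - 1)
            on_run = (tc >= run_start[ridx]) & (tc < run_end[ridx])
            pref = 1 if row.field_route == "out_left" else 2
            on_pref = on_run & (run_side[ridx] == pref)
            d = cfg.run_speed_cms * (tc - run_start[ridx])
            bump = cfg.place_amp * np.exp(
                -(d - row.field_center_cm) ** 2 / (2 * row.field_sigma_cm ** 2))
            lam = lam * np.where(on_pref, 1.0 + bump, 1.0)

        keep = rng.random(n_cand) < lam / lam_max
        st = tc[keep]
        units.append(SpikeTrain(unit_id=int(row.unit_id), region=row.region,
                                tetrode_id=int(row.tetrode_id),
                                spike_times=st,
                                mean_rate_hz=st.size / t_end,
                                spike_width_ms=float(row.width_ms)))
    return units, roster


def gen_thermocouple(cfg: SynthConfig, trials: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Nasal thermocouple proxy: sniff oscillation, faster during odor."""
    t_end = session_end_time(cfg, trials)
    fs = cfg.thermo_rate_hz
    t = np.arange(0.0, t_end, 1.0 / fs)
    f = np.full(t.size, cfg.sniff_pre_hz)
    for tr in trials.itertuples():
        f[(t >= tr.port_in) & (t < tr.port_out)] = cfg.sniff_odor_hz
    phase = 2 * np.pi * np.cumsum(f) / fs
    v = np.sin(phase + rng.uniform(0, 2 * np.pi)) \
        + 0.05 * rng.standard_normal(t.size)
    return pd.DataFrame({"t": t, "value": v})


def synthesize(cfg: Optional[SynthConfig] = None, seed: Optional[int] = None,
               with_lfp: bool = True, with_thermo: bool = True
               ) -> tuple[SessionRecord, GroundTruth]:
    """Generate one full session bundle plus its ground truth.

    Deterministic: the same (config, seed) yields a bit-identical
    session. ``seed`` overrides ``cfg.seed`` when given.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    trials = gen_trials(cfg, rng)
    position, runs = gen_position(cfg, trials, rng)
    phases = draw_session_phases(rng)
    beta_z = None
    lfp = []
    if with_lfp:
        beta_z = gen_beta_process(cfg, rng, phases,
                                  session_end_time(cfg, trials))
        lfp = gen_lfp(cfg, trials, rng, phases, beta_z)
    roster = _unit_roster(cfg, rng)
    units, roster = gen_spikes(cfg, trials, runs, rng, phases, roster,
                               beta_z)
    thermo = gen_thermocouple(cfg, trials, rng) if with_thermo else None

    t_end = session_end_time(cfg, trials)
    record = SessionRecord(
        session_id=f"synth-{cfg.seed if seed is None else seed}",
        lfp=lfp, units=units, trials=trials, position=position,
        thermocouple=thermo, epochs=[("task", 0.0, t_end)])
    truth = GroundTruth(units=roster, runs=runs,
                        pac_strength=cfg.pac_strength, config=cfg,
                        phases=phases)
    return record, truth
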