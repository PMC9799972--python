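# rhythmdecode

Analysis pipeline for multi-region extracellular recordings (hippocampal
CA1, prefrontal cortex, olfactory bulb) during an odor-cued two-choice
T-maze task, exercised end-to-end on synthetic sessions with known ground
truth.

In this task a rat samples one of two odors at a port (holding its nose
for at least 0.5 s), then runs a 123 cm route — an 80 cm center stem and a
43 cm reward arm — to the left or right reward well according to the odor.
The pipeline quantifies how rhythms and spikes organize this behavior:

- **Rhythm-band coordination** — beta (20–30 Hz) and respiratory-rhythm
  (RR, 7–8 Hz) power and cross-region coherence around odor sampling,
  from multitaper spectrograms/coherograms (DPSS tapers), with z-scored
  condition contrasts (Wilcoxon signed-rank across sessions) and circular
  cross-region phase offsets.
- **Cross-frequency coupling** — the RR-phase → beta-amplitude modulation
  index `MI = [log 18 − H(P)] / log 18`, where `P` is the normalized mean
  beta amplitude over eighteen 20° RR-phase bins, with a trial-shuffle
  permutation null.
- **Sharp-wave ripples** — 150–250 Hz envelope events exceeding
  mean + 3 SD for ≥ 15 ms on at least one CA1 tetrode, counted at the
  odor port vs the reward wells.
- **Single-unit choice coding** — selectivity index
  `SI = (λ₁ − λ₂)/(λ₁ + λ₂)` from odor-period firing rates on the two
  odors' correct trials, an odor-label shuffle null, task responsiveness
  by trial-matched signed-rank tests, and jitter-corrected (±50 ms)
  CA1→PFC cross-correlograms with max-statistic significance.
- **Spike–phase locking** — Rayleigh test with the finite-n p-value
  `p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n))`, mean vector length
  `MVL = R/n`, von Mises concentration recovered by inverting
  `A(κ) = I₁(κ)/I₀(κ)`, spike-count-matched correct-vs-incorrect MVL
  bootstraps, and population locking censuses with exact binomial tests.
- **Ensemble decoding** — PCA population-trajectory distance with a
  label-shuffle band, cross-validated GLM choice prediction over
  cumulative 0–0.1 … 0–1.0 s windows, and a memoryless Poisson Bayesian
  decoder `P(X|spikes) = C · ∏ᵢ fᵢ(X)^{spikesᵢ} · e^{−τ Σᵢ fᵢ(X)}`
  applied per 24.6 cm spatial quintile of the outbound route.
- **Spatial coding** — occupancy-normalized 2-D maps and 100-bin
  linearized tuning curves, flood-fill place fields (≥ 1 Hz peak, bounds
  at 25 % of peak, circular-shift bootstrap significance), Skaggs
  information and sparsity, and left/right trajectory selectivity.

Because real recordings are not required, the package ships a synthetic
session generator (`rhythmdecode.synth`) whose units are exact
inhomogeneous Poisson processes with choice gains, von Mises spike-timing
gains, and route-selective place fields, and whose LFP carries an RR
carrier, RR-phase-coupled beta bursts, odor-locked beta power increases,
and reward-locked ripples — every parameter recorded for recovery tests.

## Worked example

```python
import numpy as np
from rhythmdecode import SynthConfig, synthesize
from rhythmdecode import events, rhythms, pac
from rhythmdecode.session import odor_windows

record, truth = synthesize(SynthConfig(n_trials=100, seed=1))

bs = events.behavioral_summary(record.trials, record.position)
print(f"performance {bs.performance:.2f}, mean hold {bs.mean_hold_s:.2f} s")
# -> performance 0.79, mean hold 0.80 s

ca1 = record.lfp_by_region("CA1")[0]
rr = rhythms.bandpass_zero_phase(ca1, (7, 8))
beta = rhythms.bandpass_zero_phase(ca1, (20, 30))
inc = record.trials[record.trials.included]
wins = [(t.port_in - 1.5, t.reward_out) for t in inc.itertuples()]
res = pac.pac_null(rr, beta, wins, n_shuffle=500,
                   rng=np.random.default_rng(1))
print(f"RR->beta MI = {res.mi:.5f}, shuffle p = {res.p:.4f}")
# -> RR->beta MI = 0.00033, shuffle p = 0.0020
```

The MI is small in absolute terms — a 20–30 Hz filter passes only part of
an amplitude modulation at 7.5 Hz — but sits far above its trial-shuffle
null (mean ≈ 0.00001), so the coupling built into the generator
(`pac_strength = 0.5`) is detected decisively.

The numbered scripts under `analysis/` run the full study on the
reference session and write tables to `results/`:

```bash
python analysis/01_simulate_session.py --seed 1   # bundle + behavior
python analysis/02_rhythms_and_coupling.py --seed 1
python analysis/03_events_swr.py --seed 1
python analysis/04_single_units.py --seed 1
python analysis/05_ensemble_decoding.py --seed 1
python analysis/06_spatial_maps.py --seed 1
```

Representative output (seed 1): beta power rises from z ≈ +0.03 pre-odor
to +0.75 during sampling and increases post-odor in 8/8 sessions
(signed-rank p = 0.0078); SWR counts are 0.00 per odor period vs 1.14 per
reward period; correct- and incorrect-trial SI anticorrelate across
selective units (Spearman ρ = −0.98) because responses follow the chosen
side; the odor-trained Bayesian decoder beats chance only in the first
spatial quintile while quintile-trained decoding is perfect along the
whole route; and recovered place-field centers match the generator's
truth with a median error of 0.12 bins.

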