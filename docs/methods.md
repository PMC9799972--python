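# Methods

This note documents the models, estimators, and numerical choices behind
`rhythmdecode`, the design of the synthetic sessions everything is tested
on, and the limits of what those tests establish.

## Conventions

All timestamps are seconds on one monotone session clock starting at 0.
Every interval is half-open `[start, end)`, so an event on a shared
boundary is counted once; all bins are 0-based with bin `b` covering
`[b·Δ, (b+1)·Δ)`. A trial enters analysis only if the nose-poke hold
lasted at least 0.50 s (inclusive — the task enforces a *minimum* hold)
and a reward port was subsequently visited. Region labels come from the
fixed vocabulary {CA1, PFC, OB}. Phase 0 is the oscillation peak
(the analytic signal of cos ωt has argument 0 at the peak), wrapped to
[−π, π).

## Synthetic sessions

The generator (`rhythmdecode.synth`) emits complete sessions — LFP,
spikes, trials, position, thermocouple — from a single seeded RNG, so a
(config, seed) pair is bit-reproducible.

**Behavior.** Default 100 trials per session (sessions of 100–150 trials
are typical for this task), odors balanced within one trial and shuffled,
choice = odor-assigned side with probability `p_correct = 0.77`
(matching typical task performance), holds ~ Normal(0.82 s, 0.15 s)
resampled above the 0.5 s minimum. The maze is linearized to a 123 cm
outbound route (80 cm stem + 43 cm arm; the printed route length, not the
nominal 81 + 43 cm geometry, is what all spatial analyses use). Runs are
at a constant 40 cm/s with camera jitter small enough that smoothed speed
stays under the 3 cm/s run threshold during holds.

**LFP.** Per region: an RR carrier at 7.5 Hz (amplitude 0.5), a beta-band
process, and 1/f Gaussian noise (unit SD scaled by 0.5). Fixed region
phase offsets (OB leads CA1 by 0.5 rad, PFC by 0.9 rad) create the
cross-region coherence and phase-offset structure. CA1 tetrodes
additionally receive a shared train of ripple bursts (200 Hz, 50–80 ms,
Gaussian envelope) at 0.5 events/s inside reward windows.

The beta process is a complex shot-noise model: a small coherent 25 Hz
carrier (amplitude 0.12, keeping phase defined between bursts) plus
Gaussian-windowed 25 Hz wavelets (σ = 15 ms, rate 4/s, base amplitude
1.5) with **independent carrier phases** per burst and amplitudes scaled
by `1 + pac_strength · cos(φ_RR(t_burst))`. The incoherent phases are
essential: sinusoidal amplitude modulation of a coherent 25 Hz carrier at
7.5 Hz lives entirely in spectral sidebands at 17.5/32.5 Hz, which the
analysis filter (see below) attenuates ~25× in modulation depth — a
generator built that way produces coupling its own pipeline cannot see.
Burst-based coupling sits in the broadband power envelope and survives
filtering, at the cost of measured MI values that are numerically small
(~10⁻³–10⁻⁴) yet far above the trial-shuffle null. Beta amplitude
(base and bursts) is multiplied by √2 inside odor-sampling windows, i.e.
a 2× power gain; no published effect size exists for this, so it is a
synthetic choice made once to be decisively detectable at ~100 trials.

**Spikes.** Exact inhomogeneous Poisson sampling by thinning under the
intensity bound. Intensity multiplies a baseline (pyramidal 3–8 Hz,
interneuron 15–25 Hz) by three gains:

- *choice gain* `1 ± SI_target`, keyed to the **chosen** side, active
  from odor onset until 1.0 s after port exit (so choice information
  persists ~0.5 s / ~20 cm into the run — inside the first spatial
  quintile — then vanishes), plus a 1.6× odor-period rate gain that makes
  units task-responsive;
- *von Mises spike-timing gain* `exp(κ·cos(θ − μ))/I₀(κ)` with unit mean
  over phase, so κ shapes timing without changing rate; beta-band units
  lock to the argument of the complex burst process (the phase the LFP
  actually carries), RR units to the RR carrier; κ targets tile 0.3–3;
- *place gain* `1 + 6·exp(−(d − c)²/2σ²)` on the unit's preferred
  outbound route only (fields are trajectory-selective), centers tiling
  12–111 cm, σ ∈ 4–10 cm, for 75 % of pyramidal cells by default.

Realized SI equals its target in expectation because the shared factors
cancel in the rate contrast; because responses follow the chosen side,
the odor-labelled SI on incorrect trials is −SI, which is what produces
the population-level correct/incorrect anticorrelation.

**Thermocouple.** A sniff oscillation whose instantaneous frequency steps
from 6.2 Hz (pre-odor) to 7.1 Hz during odor sampling, the within-session
respiration change the pipeline's sniff-rate estimator must recover.

What the generator does **not** emulate: non-Poisson spike history
(bursting, refractoriness), theta and its speed dependence, behavioral
variability in running speed or path, electrode drift, sorting errors,
volume conduction, and any interaction between rhythms beyond RR→beta.
Passing tests therefore certify the estimators and their statistics under
the stated model, not performance on real recordings.

## Estimators and numerical choices

**Filtering.** 4th-order Butterworth, applied forward–backward
(`sosfiltfilt`, zero net phase); amplitude/phase/envelope from the
analytic signal (Hilbert transform padded to a fast FFT length).
Beta = 20–30 Hz, RR = 7–8 Hz, ripple = 150–250 Hz.

**Multitaper estimates.** DPSS tapers, defaults NW = 3 with 5 tapers,
500 ms windows, 50 ms steps. Power is trial-averaged around alignment
events; z-scoring is per frequency row against non-overlapping windows
tiling the whole recording. Coherence averages cross-/auto-spectra over
tapers within each trial-window and then averages coherence across
trials, so independent signals sit at the ~1/K taper bias floor.

**SWR detection.** Ripple-band envelope smoothed with a 4 ms Gaussian
(suppresses single-sample crossings); qualifying cores exceed
mean + 3 SD for ≥ 15 ms; event bounds extend to the envelope's return to
the mean; per-tetrode events are merged. Thresholding in SD units makes
detection invariant to amplitude scaling. On the generator's background
noise the false-event rate is < 0.5/min — rare noise events are expected
and the tests assert the absence of reward-locked *excess*, not literal
zero.

**PAC.** Eighteen 20° phase bins; MI is the KL divergence of the
normalized binned amplitude from uniform, divided by log 18 (natural
log; any base cancels). Empty bins are filled by circular neighbor
interpolation and flagged; an ε = 10⁻¹² guards the entropy. The null
permutes the trial pairing of phase and amplitude segments (truncating
each pair to the shorter member), keeping within-trial structure;
p uses the +1 permutation correction.

**Choice selectivity.** λ₁, λ₂ are duration-weighted (total spikes /
total odor-period time per odor) on correct included trials, which
avoids amplifying short-trial noise. The `selective` flag follows the
1.5-SD-from-null-mean rule; a two-sided permutation p (|SI| exceedance,
+1 corrected) is reported alongside because the 1.5 SD rule is a ~13 %
nominal level under a Gaussian null, and calibration statements need a
test at α = 0.05.

**Jitter-corrected CCG.** Lags t_PFC − t_CA1 in 2.5 ms bins over
±150 ms; the null re-histograms after jittering each PFC spike
independently within ±50 ms, 1000 times. The displayed z is pointwise
against the jitter mean/SD. Peak significance is a max-statistic
permutation test over ±100 ms with the observed CCG pooled into the
normalization, which makes the observed and surrogate max |z| values
exchangeable — an exact test; a pointwise p on the max of ~80 correlated
bins would reject almost always. Significant CCGs are smoothed with a
σ = 1 bin Gaussian for display.

**Phase locking.** Spike phases by linear interpolation of the unwrapped
band phase, re-wrapped. Rayleigh p uses the finite-n formula
`exp(√(1+4n+4(n²−R²)) − (1+2n))`, which reproduces published worked
examples to better than 10 % and approaches e^(−z) for large n. κ is
recovered by inverting A(κ) = I₁/I₀ with Brent's method on the
exponentially scaled Bessel ratio. The correct-vs-incorrect MVL
comparison draws spike-count-matched subsamples without replacement
within each of 1000 draws. The census tests locked counts against a
chance proportion equal to the α used (0.05 locally, 0.0167
Bonferroni-adjusted across three reference regions) with exact binomial
tails, and assigns multi-region-locked cells to their most significant
region.

**Decoding.** PCs are fit on the pooled trial×bin matrix (bins as
observations); the default null band for the trajectory distance is
simultaneous (95th percentile of each shuffle's maximum over bins), so a
crossing anywhere is a calibrated detection — a pointwise band over ten
correlated bins would flag ~¼ of null sessions; `band="pointwise"`
remains available. The GLM is a binomial fit on cumulative-window counts
(logit link by default; a log-link variant with logistic fallback is
provided since a log link on a binary outcome is ambiguous), 5-fold
stratified CV; significance comes from a calibrated permutation p
(fraction of label-shuffle accuracies ≥ observed, +1) with the rank-sum
p also reported. The Bayesian decoder floors rates at 0.01 Hz, decodes
in log space (verified against direct linear-space evaluation of the
likelihood), and breaks exact ties toward the choice with more training
trials. Quintile decoding uses run windows opening 0.5 s after port exit
with τ = per-trial quintile occupancy; the Monte Carlo shuffle permutes
choice identities and scores each permutation against its own labels
(scoring shuffle-trained decoders against true labels yields a bimodal
{0,1} null on separable data), with p from Gaussian statistics of 200
shuffles.

**Spatial maps.** Rates divide spikes by unsmoothed occupancy and smooth
the quotient (σ = 2 bins); spikes are snapped to the nearest position
sample rather than interpolated, because at 30 fps the tracker can skip
1.23 cm bins entirely and interpolated spikes would land in
zero-occupancy bins and vanish (this preserves the conservation
invariant rate·occupancy = spike count exactly). Flood fill extends from
the peak (ties → lowest bin) until the smoothed rate drops below 25 % of
peak; significance needs the peak to exceed mean + 2 SD of 500
circular-shift bootstraps (per-run shifts, spike counts preserved) and
field coverage < 75 % of the route.

## Validation studies

`rhythmdecode.validation` packages three study families used by the test
suite and `scripts/acceptance.py`; sizes are chosen so the battery runs
in a few minutes on one core.

**Calibration.** False-positive rates at nominal α = 0.05 over ≥ 200
seeded null runs per test: Rayleigh on uniform phases (n = 100 spikes),
the SI permutation p on rate-matched odors (40 trials), the PAC
trial-shuffle p on uncoupled signals (20 irregular trials, 200
shuffles), the jitter-CCG max-statistic test on independent 8 Hz Poisson
trains (60 s, 150 jitters), and the GLM permutation p on label-free
counts (60 trials — at 40 the 1/40 accuracy granularity creates enough
observed/null ties to push the ties-as-greater permutation p below a 2 %
rejection rate).

**Parameter recovery.** Twenty 80-trial sessions with PAC strength
spanning 0.1–0.9. SI is re-estimated per pyramidal unit; κ from
whole-session spike phases via MVL inversion, rank-compared *within*
band because the 20–30 Hz filter attenuates measured concentration
roughly twofold while the 7–8 Hz filter barely does (within-band ranks
are ~0.99; pooling bands mixes attenuation regimes); session PAC from
the whole-recording MI (odor windows alone leave the weakest sessions at
the MI noise floor). Place-field centers and widths come from tuning-
curve peaks and flood-fill bounds, excluding fields with true centers
under 30 cm — the designed choice-gain persistence elevates early-track
rates and confounds geometry there — and fields whose flood fill hits a
track end (clipped widths are not measurements). Typical results:
Spearman ρ ≈ 0.99 (SI, κ, PAC, centers) and ≈ 0.94 (widths), median
center error < 1 bin.

**Qualitative patterns.** (i) Correct/incorrect SI anticorrelation
(ρ ≈ −0.99) in a 100-trial choice-coding session; (ii) post-odor beta
power increase in 8/8 twenty-trial sessions (signed-rank p = 0.0078, the
minimum for n = 8); (iii) quintile decoding on two dedicated designs —
transient choice tuning without fields (odor-trained decoder above
chance only in quintile 1) and all-cell route-selective fields
(quintile-trained decoder above chance in all five). These are asserted
as orderings: the per-quintile shuffle test is approximately calibrated,
so individual later quintiles reach p < 0.05 at roughly the nominal rate
and "none significant" would fail for about a quarter of seeds by
construction. In the default generator both codes coexist, and the
odor-trained decoder then picks up route-correlated place firing in
later quintiles with arbitrary sign — visible in
`analysis/05_ensemble_decoding.py`, which therefore uses the dedicated
designs for this comparison.

## Known limitations

- Statistical, not biophysical, emulation; see the generator caveats
  above. Effect sizes without published values are synthetic choices.
- Measured MI and MVL are attenuated by the band filters (a property of
  any such pipeline); recovery claims are about rank order, not absolute
  values.
- The even/odd PCA control and the pointwise quintile p-values inherit
  the usual multiple-comparison caveats; defaults use simultaneous bands
  or ordering assertions where calibration matters.
- `sniff_rate` is a peak-counting estimator and assumes a clean
  thermocouple trace; it has no artifact rejection.
- The bundle format stores LFP/spikes in HDF5 with trials/position as
  CSV; no reader exists for raw acquisition formats, and spike sorting
  is out of scope.
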