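"""Population-level choice decoding.

Three complementary reads of the same question — does ensemble activity
during (and after) odor sampling predict the upcoming T-maze choice?

* PCA trajectory distance: project per-bin population vectors onto the
  first three PCs, measure the Euclidean distance between choice-averaged
  trajectories per 100 ms bin, and compare against a label-shuffle null.
* GLM prediction: cross-validated binomial GLM on cumulative-window spike
  counts (0-0.1 s ... 0-1.0 s from odor onset).
* Memoryless Poisson Bayesian decoder trained on odor-period rates (or on
  per-quintile run rates) and applied to the spike counts of each spatial
  quintile of the 123 cm outbound route:
  P(X|spikes) = C * prod_i f_i(X)^{spikes_i} * exp(-tau * sum_i f_i(X)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .session import SpikeTrain, count_in_window
from .spatial import N_QUINTILES, QUINTILE_CM

RATE_BIN_S = 0.1
RATE_FLOOR_HZ = 0.01


class SessionSkip(Exception):
    """Session does not meet the inclusion threshold (e.g. < 4 units)."""


@dataclass
class RateMatrix:
    values: np.ndarray             # (trials, bins, units), Hz
    unit_ids: list[int]
    trial_ids: np.ndarray
    bin_edges: np.ndarray          # s relative to alignment event
    alignment: str


@dataclass
class TrajectoryDiscrimination:
    pc_coords: dict                # choice -> (bins, 3)
    dist: np.ndarray
    null_upper: np.ndarray
    evenodd_dist: np.ndarray
    discrimination_time_s: Optional[float]
    band: str                      # simultaneous | pointwise


@dataclass
class BayesDecoder:
    f: np.ndarray                  # (units, 2) mean rates, floored
    unit_ids: list[int]
    n_train: np.ndarray            # training trials per choice


def build_rate_matrix(units: Sequence[SpikeTrain], trials: pd.DataFrame,
                      alignment: str = "odor_on",
                      window: tuple[float, float] = (0.0, 1.0),
                      bin_s: float = RATE_BIN_S) -> RateMatrix:
    """Per-trial binned firing rates aligned to an event.

    ``alignment`` is ``odor_on`` (port entry) or ``port_out``. Sessions
    with fewer than four units raise :class:`SessionSkip`.
    """
    if len(units) < 4:
        raise SessionSkip("fewer than 4 task-responsive units")
    inc = trials[trials["included"]]
    anchor = inc["port_in"] if alignment == "odor_on" else inc["port_out"]
    anchor = anchor.to_numpy(float)
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    n_bins = edges.size - 1
    vals = np.zeros((len(inc), n_bins, len(units)))
    for j, u in enumerate(units):
        for i, a in enumerate(anchor):
            for b in range(n_bins):
                vals[i, b, j] = count_in_window(
                    u.spike_times, a + edges[b], a + edges[b + 1]) / bin_s
    return RateMatrix(values=vals, unit_ids=[u.unit_id for u in units],
                      trial_ids=inc["trial_id"].to_numpy(),
                      bin_edges=edges, alignment=alignment)


# ---------------------------------------------------------------------------
# PCA trajectory discrimination
# ---------------------------------------------------------------------------

def _mean_traj_distance(proj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-bin distance between choice-averaged projected trajectories."""
    m1 = proj[labels == 1].mean(axis=0)
    m2 = proj[labels == 2].mean(axis=0)
    return np.linalg.norm(m1 - m2, axis=-1)


def pca_discrimination(rm: RateMatrix, labels: np.ndarray,
                       n_shuffle: int = 500,
                       rng: Optional[np.random.Generator] = None,
                       n_pcs: int = 3,
                       band: str = "simultaneous") -> TrajectoryDiscrimination:
    """Choice separation of population trajectories in PC space.

    PCs are fit on the pooled trial-by-bin matrix (bins as observations).
    The null recomputes the per-bin distance after shuffling choice
    labels; by default the 95% band is simultaneous (computed from each
    shuffle's maximum over bins) so a single crossing anywhere is a
    calibrated detection, with ``band="pointwise"`` available. The
    even/odd control splits trials within each choice and averages the
    two within-choice distances.
    """
    rng = rng or np.random.default_rng()
    labels = np.asarray(labels)
    if min((labels == 1).sum(), (labels == 2).sum()) < 5:
        raise ValueError("need >= 5 trials of each choice")
    n_tr, n_bins, n_units = rm.values.shape
    flat = rm.values.reshape(n_tr * n_bins, n_units)
    k = min(n_pcs, min(flat.shape) - 1, np.linalg.matrix_rank(flat))
    if k < n_pcs:
        warnings.warn(f"rank-deficient rate matrix: using {k} PCs")
    pca = PCA(n_components=k)
    proj = pca.fit_transform(flat).reshape(n_tr, n_bins, k)

    dist = _mean_traj_distance(proj, labels)
    null = np.empty((n_shuffle, n_bins))
    for s in range(n_shuffle):
        null[s] = _mean_traj_distance(proj, rng.permutation(labels))
    if band == "simultaneous":
        upper = np.full(n_bins, np.percentile(null.max(axis=1), 95))
    elif band == "pointwise":
        upper = np.percentile(null, 97.5, axis=0)
    else:
        raise ValueError(f"unknown band {band!r}")

    # even/odd control: within-choice split distances, averaged
    eo = np.zeros(n_bins)
    for c in (1, 2):
        idx = np.where(labels == c)[0]
        even, odd = idx[::2], idx[1::2]
        eo += np.linalg.norm(proj[even].mean(axis=0)
                             - proj[odd].mean(axis=0), axis=-1)
    eo /= 2.0

    centers = (rm.bin_edges[:-1] + rm.bin_edges[1:]) / 2
    exceed = np.where(dist > upper)[0]
    t_disc = float(centers[exceed[0]]) if exceed.size else None
    coords = {c: proj[labels == c].mean(axis=0) for c in (1, 2)}
    return TrajectoryDiscrimination(pc_coords=coords, dist=dist,
                                    null_upper=upper, evenodd_dist=eo,
                                    discrimination_time_s=t_disc, band=band)


# ---------------------------------------------------------------------------
# GLM choice prediction
# ---------------------------------------------------------------------------

def _cv_accuracy(X: np.ndarray, y: np.ndarray, k: int,
                 rng: np.random.Generator, link: str) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    correct = 0
    for tr_idx, te_idx in skf.split(X, y):
        if link == "log":
            import statsmodels.api as sm
            try:
                fit = sm.GLM(y[tr_idx] - 1, sm.add_constant(X[tr_idx]),
                             family=sm.families.Binomial(
                                 sm.families.links.Log())).fit()
                pred = (fit.predict(sm.add_constant(X[te_idx],
                                                    has_constant="add"))
                        > 0.5).astype(int) + 1
            except Exception:  # log link can leave the mean space
                pred = _logit_predict(X, y, tr_idx, te_idx)
        else:
            pred = _logit_predict(X, y, tr_idx, te_idx)
        correct += int(np.sum(pred == y[te_idx]))
    return correct / y.size


def _logit_predict(X, y, tr_idx, te_idx):
    # liblinear: fastest solver for these small dense binary problems
    clf = LogisticRegression(max_iter=2000, solver="liblinear")
    clf.fit(X[tr_idx], y[tr_idx])
    return clf.predict(X[te_idx])


def glm_choice_prediction(rm: RateMatrix, labels: np.ndarray,
                          k: int = 5, n_shuffle: int = 100,
                          rng: Optional[np.random.Generator] = None,
                          link: str = "logit") -> pd.DataFrame:
    """Cross-validated choice prediction over cumulative windows.

    For each window 0-0.1 s ... 0-1.0 s the per-unit cumulative counts
    feed a binomial GLM (logit link by default; ``link="log"`` fits a
    log-binomial with logistic fallback). Accuracy is compared against a
    label-shuffle null two ways: a permutation p (fraction of shuffle
    accuracies >= observed, +1 corrected — calibrated) and the rank-sum
    p of the observed accuracy against the null accuracies.
    """
    rng = rng or np.random.default_rng()
    labels = np.asarray(labels)
    if labels.size < 20:
        raise ValueError("need >= 20 trials")
    n_tr, n_bins, _ = rm.values.shape
    rows = []
    for w in range(1, n_bins + 1):
        X = rm.values[:, :w, :].mean(axis=1)
        acc = _cv_accuracy(X, labels, k, rng, link)
        null = np.array([_cv_accuracy(X, rng.permutation(labels), k, rng,
                                      link) for _ in range(n_shuffle)])
        p_perm = (1 + int(np.sum(null >= acc))) / (1 + n_shuffle)
        p_rank = float(stats.mannwhitneyu(
            [acc], null, alternative="greater").pvalue)
        rows.append(dict(window_s=w * RATE_BIN_S, accuracy=acc,
                         null_mean=float(null.mean()), p_perm=p_perm,
                         p_ranksum=p_rank))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian decoder
# ---------------------------------------------------------------------------

def bayes_train(counts: np.ndarray, durations: np.ndarray,
                labels: np.ndarray, unit_ids: Optional[Sequence[int]] = None
                ) -> BayesDecoder:
    """Per-choice mean rates from training spike counts.

    ``counts`` is (trials, units); ``durations`` per trial (s). Rates are
    total spikes / total time per choice, floored at 0.01 Hz.
    """
    labels = np.asarray(labels)
    n_units = counts.shape[1]
    f = np.empty((n_units, 2))
    n_train = np.empty(2, int)
    for c in (1, 2):
        m = labels == c
        if not m.any():
            raise ValueError(f"no training trials for choice {c}")
        f[:, c - 1] = counts[m].sum(axis=0) / durations[m].sum()
        n_train[c - 1] = int(m.sum())
    f = np.maximum(f, RATE_FLOOR_HZ)
    return BayesDecoder(f=f, unit_ids=list(unit_ids or range(n_units)),
                        n_train=n_train)


def bayes_decode(decoder: BayesDecoder, spike_counts: np.ndarray,
                 tau: float) -> tuple[np.ndarray, int]:
    """Posterior over the two choices from one window's spike counts.

    Log-likelihood l(X) = sum_i spikes_i * log f_i(X) - tau * sum_i f_i(X)
    with a uniform prior; the posterior is the softmax over choices.
    Ties decode to the choice with more training trials.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    counts = np.asarray(spike_counts, float)
    if np.any(counts < 0):
        raise ValueError("negative spike counts")
    ll = counts @ np.log(decoder.f) - tau * decoder.f.sum(axis=0)
    ll -= ll.max()
    post = np.exp(ll)
    post /= post.sum()
    if post[0] == post[1]:
        choice = 1 + int(np.argmax(decoder.n_train))
    else:
        choice = 1 + int(np.argmax(post))
    return post, choice


def bayes_decode_linear(decoder: BayesDecoder, spike_counts: np.ndarray,
                        tau: float) -> np.ndarray:
    """Direct linear-space evaluation of the decoder equation (oracle).

    Computes C * prod_i f_i(X)^{spikes_i} * exp(-tau sum_i f_i(X)) without
    logarithms; underflows for large problems, used for cross-checking.
    """
    counts = np.asarray(spike_counts, float)
    like = np.prod(decoder.f ** counts[:, None], axis=0) \
        * np.exp(-tau * decoder.f.sum(axis=0))
    return like / like.sum()


# ---------------------------------------------------------------------------
# quintile decoding
# ---------------------------------------------------------------------------

def quintile_occupancy(runs: pd.DataFrame, port_out: pd.Series,
                       start_delay_s: float = 0.5) -> pd.DataFrame:
    """Entry/exit times of each outbound run in each spatial quintile.

    Run windows start 0.5 s after odor-port exit (to keep odor-period
    and run spikes disjoint) while speed stays above threshold (runs are
    already speed-gated). Quintile q spans [q*24.6, (q+1)*24.6) cm.
    """
    rows = []
    for r in runs.itertuples():
        tid_t0 = None
        for q in range(N_QUINTILES):
            lo, hi = q * QUINTILE_CM, (q + 1) * QUINTILE_CM
            m = (r.linear_cm >= lo) & (r.linear_cm < hi)
            if not m.any():
                continue
            t0, t1 = float(r.t[m][0]), float(r.t[m][-1])
            rows.append(dict(start=r.start, route=r.route, quintile=q,
                             t_enter=t0, t_exit=t1))
    return pd.DataFrame(rows)


def decode_choice_by_quintile(units: Sequence[SpikeTrain],
                              trials: pd.DataFrame, runs: pd.DataFrame,
                              mode: str = "odor_period",
                              n_shuffle: int = 200, k: int = 5,
                              rng: Optional[np.random.Generator] = None,
                              start_delay_s: float = 0.5) -> pd.DataFrame:
    """Choice decoding per spatial quintile with a shuffle null.

    ``mode="odor_period"`` trains the decoder once on odor-sampling
    spikes; ``mode="spatial_quintile"`` trains separately per quintile on
    the training trials' quintile rates. Testing always uses the test
    trials' quintile spike counts with tau = per-trial quintile occupancy.
    Folds are stratified by choice; p comes from Gaussian statistics of
    an ``n_shuffle`` Monte Carlo shuffle of training-set choice labels.
    """
    rng = rng or np.random.default_rng()
    inc = trials[trials["included"]].reset_index(drop=True)
    # align runs to trials via run start falling between port_out and reward_out
    run_by_trial = {}
    for r in runs.itertuples():
        m = inc[(inc["port_out"] <= r.start) & (inc["reward_out"] > r.start)]
        if len(m):
            run_by_trial[int(m.iloc[0]["trial_id"])] = r
    kept = inc[inc["trial_id"].isin(run_by_trial)].reset_index(drop=True)
    labels = kept["choice"].to_numpy(int)
    n_trials = len(kept)
    n_units = len(units)

    # odor-period counts and durations (training data for odor mode)
    odor_counts = np.zeros((n_trials, n_units))
    odor_durs = np.zeros(n_trials)
    for i, tr in enumerate(kept.itertuples()):
        start = tr.port_in
        odor_durs[i] = tr.port_out - tr.port_in
        for j, u in enumerate(units):
            odor_counts[i, j] = count_in_window(u.spike_times, start,
                                                tr.port_out)

    # per-quintile counts and occupancy durations
    q_counts = np.full((n_trials, N_QUINTILES, n_units), np.nan)
    q_durs = np.full((n_trials, N_QUINTILES), np.nan)
    for i, tr in enumerate(kept.itertuples()):
        r = run_by_trial[int(tr.trial_id)]
        t_min = tr.port_out + start_delay_s
        for q in range(N_QUINTILES):
            lo, hi = q * QUINTILE_CM, (q + 1) * QUINTILE_CM
            m = (r.linear_cm >= lo) & (r.linear_cm < hi) & (r.t >= t_min)
            if not m.any():
                continue
            t0, t1 = float(r.t[m][0]), float(r.t[m][-1]) + 1e-9
            q_durs[i, q] = t1 - t0
            for j, u in enumerate(units):
                q_counts[i, q, j] = count_in_window(u.spike_times, t0, t1)

    def _accuracy(perm_labels: np.ndarray) -> np.ndarray:
        acc = np.zeros(N_QUINTILES)
        tested = np.zeros(N_QUINTILES)
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for tr_idx, te_idx in skf.split(np.zeros(n_trials), perm_labels):
            if mode == "odor_period":
                dec = bayes_train(odor_counts[tr_idx], odor_durs[tr_idx],
                                  perm_labels[tr_idx])
                decs = [dec] * N_QUINTILES
            elif mode == "spatial_quintile":
                decs = []
                for q in range(N_QUINTILES):
                    ok = tr_idx[np.isfinite(q_durs[tr_idx, q])]
                    decs.append(bayes_train(q_counts[ok, q], q_durs[ok, q],
                                            perm_labels[ok]))
            else:
                raise ValueError(f"unknown mode {mode!r}")
            for i in te_idx:
                for q in range(N_QUINTILES):
                    if not np.isfinite(q_durs[i, q]):
                        continue  # trial never entered this quintile
                    _, choice = bayes_decode(decs[q], q_counts[i, q],
                                             q_durs[i, q])
                    # shuffles score against their own permuted labels, so
                    # the null is binomial around chance rather than the
                    # bimodal artifact of mixing shuffled training with
                    # true evaluation labels
                    acc[q] += choice == perm_labels[i]
                    tested[q] += 1
        return acc / np.maximum(tested, 1)

    observed = _accuracy(labels)
    null = np.stack([_accuracy(rng.permutation(labels))
                     for _ in range(n_shuffle)])
    mu, sd = null.mean(axis=0), null.std(axis=0)
    sd[sd == 0] = 1e-12
    p = stats.norm.sf((observed - mu) / sd)
    return pd.DataFrame(dict(quintile=np.arange(N_QUINTILES),
                             accuracy=observed, null_mean=mu, null_sd=sd,
                             p=p))
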