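"""Rank structure of single-trial decoder projections.

Projections of each trial's activity onto trial-type coding directions are
converted to relative ranks across trials (rank 1 = largest projection,
ties averaged).  The statistics here quantify how well a trial's rank is
preserved across behavioral epochs, across neighboring trials, and over the
whole session — the signatures of slow internal states — plus the
neuron-shuffle control that destroys within-trial coupling while exactly
preserving every neuron's PSTH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RankMatrix",
    "rank_transform",
    "epoch_rank_consistency",
    "rank_dynamics_consistency",
    "adjacent_pair_stats",
    "long_timescale_rank_corr",
    "reference_rank_similarity",
    "shuffle_control",
]


@dataclass
class RankMatrix:
    """Trials x bins ranks of projections within one group of trials.

    ``ranks[i, t]`` is trial i's rank at bin t (1 = largest projection, ties
    averaged); ``normalized`` divides by the group's trial count;
    ``trial_indices`` are the trials' positions in the parent session.
    """

    ranks: np.ndarray
    group: str
    trial_indices: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        return self.ranks / self.ranks.shape[0]

    @property
    def n_trials(self) -> int:
        return self.ranks.shape[0]


def _rank_columns(values: np.ndarray) -> np.ndarray:
    """Per-column descending average ranks (1 = largest)."""
    return np.apply_along_axis(lambda c: stats.rankdata(-c, method="average"),
                               0, values)


def rank_transform(projections, grouping: str = "within_type", labels=None) -> dict:
    """Per-bin relative ranks of projections.

    ``projections``: (trials, T).  ``grouping='within_type'`` ranks trials
    separately within each label group (requires ``labels``);
    ``grouping='pooled'`` ranks across all trials.  Returns a dict mapping
    group name to :class:`RankMatrix`.
    """
    P = np.asarray(projections, dtype=float)
    if grouping == "pooled":
        if P.shape[0] < 3:
            raise ValueError("need at least 3 trials")
        return {"pooled": RankMatrix(ranks=_rank_columns(P), group="pooled",
                                     trial_indices=np.arange(P.shape[0]))}
    if grouping != "within_type":
        raise ValueError(f"unknown grouping {grouping!r}")
    labels = np.asarray(labels)
    out = {}
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 3:
            raise ValueError(f"need at least 3 trials in group {g!r}")
        out[str(g)] = RankMatrix(ranks=_rank_columns(P[idx]), group=str(g),
                                 trial_indices=idx)
    return out


def epoch_rank_consistency(projections, schedule, labels) -> dict:
    """Spearman correlation of trials' epoch-averaged projections between
    adjacent epochs, within trial type.

    Returns ``{(type, 'epochA->epochB'): rho}`` (NaN when a type has fewer
    than 3 trials).
    """
    P = np.asarray(projections, dtype=float)
    labels = np.asarray(labels)
    epoch_means = np.stack([P[:, schedule.bins_of(s)].mean(axis=1)
                            for s in range(schedule.n_epochs)], axis=1)
    out = {}
    for g in np.unique(labels):
        idx = labels == g
        for s in range(schedule.n_epochs - 1):
            key = (str(g), f"{schedule.labels[s]}->{schedule.labels[s + 1]}")
            if idx.sum() < 3:
                out[key] = np.nan
                continue
            rho, _ = stats.spearmanr(epoch_means[idx, s], epoch_means[idx, s + 1])
            out[key] = float(rho)
    return out


def rank_dynamics_consistency(rank_i, rank_j, signed: bool = False) -> float:
    """Consistency of within-epoch rank change between two trials.

    The default follows the as-printed statistic: the absolute centered
    cross-moment of the two rank time-courses over the epoch's bins, divided
    by the product of their standard deviations (|Pearson| on ranks).  The
    signed flag gives the ordinary signed Pearson correlation.  Returns NaN
    when either trial's rank is constant over the epoch.
    """
    ri = np.asarray(rank_i, dtype=float)
    rj = np.asarray(rank_j, dtype=float)
    if ri.shape != rj.shape or ri.ndim != 1 or len(ri) < 3:
        raise ValueError("need two equal-length rank time-courses (>=3 bins)")
    si, sj = ri.std(), rj.std()
    if si == 0 or sj == 0:
        return np.nan
    num = np.mean((ri - ri.mean()) * (rj - rj.mean()))
    r = num / (si * sj)
    return float(r) if signed else float(abs(r))


def adjacent_pair_stats(projections, labels, schedule, signed: bool = False) -> dict:
    """Rank-dynamics consistency r_s(i, i+1) for consecutive same-type trials.

    Trials are taken in session order; pairs qualify only when trial i+1 has
    the same type as trial i.  Ranks are within-type.  Returns
    ``{epoch_label: array of r_s values}`` (empty arrays when no pairs).
    """
    P = np.asarray(projections, dtype=float)
    labels = np.asarray(labels)
    rank_by_type = rank_transform(P, "within_type", labels)
    # map session trial index -> (type, row in its rank matrix)
    row_of = {}
    for g, rm in rank_by_type.items():
        for row, idx in enumerate(rm.trial_indices):
            row_of[idx] = (g, row)
    out = {lab: [] for lab in schedule.labels}
    for i in range(P.shape[0] - 1):
        if labels[i] != labels[i + 1]:
            continue
        g, ri = row_of[i]
        _, rj = row_of[i + 1]
        rm = rank_by_type[g]
        for s, lab in enumerate(schedule.labels):
            bins = schedule.bins_of(s)
            if len(bins) < 3:
                continue
            out[lab].append(rank_dynamics_consistency(
                rm.ranks[ri, bins], rm.ranks[rj, bins], signed=signed))
    return {lab: np.asarray(v) for lab, v in out.items()}


def long_timescale_rank_corr(projections, labels, schedule,
                             method: str = "pearson") -> dict:
    """Correlation of a trial's temporal position in the session with its
    within-type, epoch-averaged activity rank.

    Returns ``{(type, epoch_label): r}``; requires >= 10 trials per type.
    """
    P = np.asarray(projections, dtype=float)
    labels = np.asarray(labels)
    out = {}
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 10:
            raise ValueError(f"need >= 10 trials of type {g!r}")
        for s, lab in enumerate(schedule.labels):
            means = P[idx][:, schedule.bins_of(s)].mean(axis=1)
            rank = stats.rankdata(-means, method="average")
            if method == "pearson":
                r = stats.pearsonr(idx.astype(float), rank)[0]
            elif method == "spearman":
                r = stats.spearmanr(idx.astype(float), rank)[0]
            else:
                raise ValueError(f"unknown method {method!r}")
            out[(str(g), lab)] = float(r)
    return out


def reference_rank_similarity(projections, correct_mask, bin_centers_s,
                              delay_onset_s: float, window_s=(-0.3, 0.0)) -> dict:
    """Per-bin Spearman similarity of instantaneous pooled trial ranks to the
    late-sample reference rank (ranks averaged over the window ending at
    delay onset), computed separately over correct and error trials.

    Returns ``{'correct': (T,), 'error': (T,) or None}``; the error series is
    omitted (with a warning) below 5 error trials.
    """
    P = np.asarray(projections, dtype=float)
    correct_mask = np.asarray(correct_mask, dtype=bool)
    centers = np.asarray(bin_centers_s, dtype=float)
    ranks = rank_transform(P, "pooled")["pooled"].ranks
    ref_bins = (centers >= delay_onset_s + window_s[0]) & (centers <= delay_onset_s + window_s[1])
    if not ref_bins.any():
        raise ValueError("reference window contains no bins")
    ref = ranks[:, ref_bins].mean(axis=1)
    out = {}
    for tag, mask in (("correct", correct_mask), ("error", ~correct_mask)):
        if mask.sum() < 5:
            if tag == "error":
                warnings.warn("fewer than 5 error trials; error similarity omitted")
                out[tag] = None
                continue
            raise ValueError("fewer than 5 correct trials")
        sim = np.array([stats.spearmanr(ranks[mask, t], ref[mask])[0]
                        for t in range(ranks.shape[1])])
        out[tag] = sim
    return out


def shuffle_control(values, labels, seed=None) -> np.ndarray:
    """Neuron-shuffle control: each neuron's single-trial activity is
    replaced by the same neuron's activity on another random trial of the
    same trial type (independent permutation per neuron, per type).

    ``values``: (trials, neurons, bins).  Exactly preserves every neuron's
    per-type PSTH; destroys within-trial coupling across neurons.
    """
    rng = np.random.default_rng(seed)
    V = np.array(values, dtype=float, copy=True)
    labels = np.asarray(labels)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        for u in range(V.shape[1]):
            perm = rng.permutation(idx)
            V[idx, u, :] = values[perm, u, :]
    return V
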