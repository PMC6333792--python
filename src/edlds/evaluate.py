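"""Cross-validated goodness-of-fit for the state-space model.

The central measure is leave-one-neuron-out (LONO) variance explained: the
activity of one neuron is removed from held-out trials, the latent
trajectory is inferred from the remaining neurons, and the held-out
neuron's activity is predicted through its emission row.  Explained
variance is

    R^2 = 1 - < <||r_i - r̂_i||^2>_t / <||r_i - r0_i||^2>_t >_i

with <.>_t averaging over bins and trials and <.>_i over neurons; the
denominator deviates from the per-neuron training mean r0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import EDLDSParams, EpochSchedule, em_fit, kalman_smooth

__all__ = [
    "LonoResult",
    "DimSelection",
    "lono_r2",
    "psth_baseline_r2",
    "fit_baseline_variants",
    "select_dim",
    "pick_dimension",
    "error_trial_generalization",
]


@dataclass
class LonoResult:
    r2: float
    per_neuron_r2: np.ndarray
    model_tag: str = "EDLDS"
    subset_tag: str = "correct"


@dataclass
class DimSelection:
    dims: np.ndarray
    r2: np.ndarray
    selected: int

    def to_dict(self) -> dict:
        return {"dims": self.dims.tolist(), "r2": self.r2.tolist(),
                "selected": int(self.selected)}


def _r2_from_errors(sq_err, sq_dev):
    """Eq.-style aggregation: per-neuron error ratios, then neuron average."""
    ratio = sq_err / np.where(sq_dev > 0, sq_dev, np.nan)
    per_neuron = 1.0 - ratio
    return float(np.nanmean(per_neuron)), per_neuron


def lono_r2(params: EDLDSParams, schedule: EpochSchedule, Y,
            model_tag: str = "EDLDS", subset_tag: str = "correct") -> LonoResult:
    """Leave-one-neuron-out explained variance of ``params`` on test trials.

    ``Y``: (n_trials, T, N) activity from trials disjoint from those used to
    fit ``params``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[None]
    n, T, N = Y.shape
    if N < 2:
        raise ValueError("LONO requires at least 2 neurons")
    if N != params.N:
        raise ValueError("neuron count mismatch")
    epoch = schedule.epoch_of_bin
    sq_err = np.empty(N)
    sq_dev = np.empty(N)
    for i in range(N):
        sub = params.drop_neuron(i)
        keep = np.arange(N) != i
        post = kalman_smooth(sub, schedule, Y[:, :, keep])
        # predict neuron i through its epoch-indexed emission row
        Wrow = params.W_proj[:, i, :]                     # (S, M)
        pred = np.einsum("ntm,tm->nt", post.smoothed_means, Wrow[epoch]) + params.r0[i]
        sq_err[i] = np.mean((Y[:, :, i] - pred) ** 2)
        sq_dev[i] = np.mean((Y[:, :, i] - params.r0[i]) ** 2)
    r2, per_neuron = _r2_from_errors(sq_err, sq_dev)
    return LonoResult(r2=r2, per_neuron_r2=per_neuron,
                      model_tag=model_tag, subset_tag=subset_tag)


def psth_baseline_r2(train_Y, test_Y, train_conditions, test_conditions,
                     r0=None, subset_tag: str = "correct") -> LonoResult:
    """Mean-activity (PSTH) reference model.

    The prediction for each neuron and bin is the training-set mean within
    the trial's condition (correct/error x contra/ipsi); explained variance
    follows the same formula as :func:`lono_r2`.
    """
    train_Y = np.asarray(train_Y, dtype=float)
    test_Y = np.asarray(test_Y, dtype=float)
    train_conditions = np.asarray(train_conditions)
    test_conditions = np.asarray(test_conditions)
    N = train_Y.shape[2]
    if r0 is None:
        r0 = train_Y.reshape(-1, N).mean(axis=0)
    grand = train_Y.mean(axis=0)                          # (T, N)
    psth = {}
    for c in np.unique(train_conditions):
        psth[c] = train_Y[train_conditions == c].mean(axis=0)
    pred = np.empty_like(test_Y)
    for j, c in enumerate(test_conditions):
        if c in psth:
            pred[j] = psth[c]
        else:
            warnings.warn(f"condition {c!r} unseen in training; using grand mean")
            pred[j] = grand
    sq_err = np.mean((test_Y - pred) ** 2, axis=(0, 1))
    sq_dev = np.mean((test_Y - r0) ** 2, axis=(0, 1))
    r2, per_neuron = _r2_from_errors(sq_err, sq_dev)
    return LonoResult(r2=r2, per_neuron_r2=per_neuron,
                      model_tag="PSTH", subset_tag=subset_tag)


def fit_baseline_variants(Y, schedule, M, variant: str, **em_kwargs):
    """Fit a tied-parameter variant: ``'lds'`` (both matrices constant across
    epochs), ``'const_wmode'``, or ``'const_wproj'``."""
    if variant not in ("lds", "const_wmode", "const_wproj"):
        raise ValueError(f"unknown baseline variant {variant!r}")
    return em_fit(Y, schedule, M, variant=variant, **em_kwargs)


def pick_dimension(dims, r2) -> int:
    """Minimal candidate dimension reaching 90% of the maximal R^2 (signed
    scale); ties go to the smaller dimension."""
    dims = np.asarray(dims)
    r2 = np.asarray(r2, dtype=float)
    best = np.nanmax(r2)
    crit = best - 0.1 * abs(best)      # = 0.9 * best for positive best
    ok = np.flatnonzero(r2 >= crit)
    return int(dims[ok[0]])


def select_dim(Y, schedule, dims, labels=None, folds: int = 10, seed: int = 0,
               **em_kwargs) -> DimSelection:
    """Cross-validated latent-dimension selection.

    For each candidate dimension, k-fold CV (stratified by trial type when
    labels are given): fit on the training folds, LONO R^2 on the held-out
    fold; the selected dimension is the minimal one reaching 90% of the
    maximal cross-validated R^2.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n < 2 * folds:                     # every fold needs >= 2 trials
        new_folds = max(2, n // 2)
        if new_folds < 2:
            raise ValueError("too few trials for cross-validation")
        warnings.warn(f"reduced folds {folds} -> {new_folds} (too few trials)")
        folds = new_folds
    if labels is not None:
        labels = np.asarray(labels)
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = list(splitter.split(Y, labels))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = list(splitter.split(Y))
    dims = np.asarray(list(dims))
    r2 = np.empty(len(dims))
    for k, M in enumerate(dims):
        num = den = 0.0
        for tr_idx, te_idx in split:
            params, _ = em_fit(Y[tr_idx], schedule, int(M), seed=seed, **em_kwargs)
            res = lono_r2(params, schedule, Y[te_idx])
            num += res.r2 * len(te_idx)
            den += len(te_idx)
        r2[k] = num / den
    return DimSelection(dims=dims, r2=r2, selected=pick_dimension(dims, r2))


def error_trial_generalization(params: EDLDSParams, schedule: EpochSchedule,
                               error_Y, psth_reference_r2: float | None = None) -> dict:
    """Evaluate correct-trial parameters on error trials.

    Returns ``{'r2_error', 'ratio_to_psth'}``; the ratio divides the model's
    error-trial explained variance by the PSTH reference's explained
    variance on the same trials.  Zero error trials yields an empty dict.
    """
    error_Y = np.asarray(error_Y, dtype=float)
    if error_Y.size == 0 or error_Y.shape[0] == 0:
        return {}
    res = lono_r2(params, schedule, error_Y, subset_tag="error")
    out = {"r2_error": res.r2}
    if psth_reference_r2 is not None:
        out["ratio_to_psth"] = (res.r2 / psth_reference_r2
                                if psth_reference_r2 > 0 else np.nan)
    return out
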