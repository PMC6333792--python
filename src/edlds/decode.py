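"""Linear and nonlinear decoders of behavioral variables from population
activity or latent trajectories.

Trial-type decoding uses a sparse linear discriminant: the Fisher
discriminant ratio with the sample covariance shrunk toward its diagonal
(weight ``gamma``) and an L1 penalty (weight ``delta``), the weight vector
normalized to unit L2 norm and signed so contra-trial projections are
negative.  Correctness and previous-trial decoding additionally use a
2nd-order polynomial-kernel SVM (kernel (1 + <r_i r_j>)^2) and QDA on
instantaneous bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DecoderModel",
    "DecodabilityCurve",
    "fit_sparse_lda",
    "tune_lda",
    "project",
    "window_average",
    "trial_type_decodability",
    "rt_correlation",
    "correctness_decodability",
    "onset_time",
    "previous_trial_decoding",
    "decoder_similarity",
    "poly2_kernel",
]


@dataclass
class DecoderModel:
    weights: np.ndarray                 # unit L2 norm
    gamma: float
    delta: float
    center: np.ndarray                  # training-feature grand mean
    threshold: float                    # decision threshold on centered projection
    classes: tuple = ("contra", "ipsi")  # (negative, positive)
    feature_space: str = "FNS"

    def decision_value(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.center) @ self.weights

    def predict(self, X) -> np.ndarray:
        s = self.decision_value(X)
        return np.where(s < self.threshold, self.classes[0], self.classes[1])


@dataclass
class DecodabilityCurve:
    accuracy: np.ndarray
    std: np.ndarray
    bin_centers_s: np.ndarray
    family: str
    label_type: str
    balanced: bool = False


def _soft(x, thr):
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def _sparse_discriminant(d, Sigma_r, delta, max_iter=500, tol=1e-9):
    """Coordinate descent on 1/2 l'Ql - d'l + delta*|l|_1 (Q = Sigma_r)."""
    p = len(d)
    diag = np.diag(Sigma_r).copy()
    diag[diag <= 0] = 1e-12
    l = np.zeros(p)
    # scale so the problem is well-conditioned regardless of feature units
    for _ in range(max_iter):
        l_old = l.copy()
        for j in range(p):
            r_j = d[j] - Sigma_r[j] @ l + diag[j] * l[j]
            l[j] = _soft(r_j, delta) / diag[j]
        if np.max(np.abs(l - l_old)) < tol * (1 + np.max(np.abs(l))):
            break
    return l


def fit_sparse_lda(X, labels, gamma: float = 0.0, delta: float = 0.0,
                   classes: tuple | None = None,
                   feature_space: str = "FNS") -> DecoderModel:
    """Fit the sparse discriminant on per-trial features.

    ``X``: (n_trials, n_features); ``labels``: two classes, the first of
    ``classes`` (default the lexicographically ordered pair, with 'contra'
    first when present) is assigned negative projections.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = list(np.unique(labels))
    if len(uniq) != 2:
        raise ValueError("exactly two classes required")
    if classes is None:
        if "contra" in uniq:
            classes = ("contra", [u for u in uniq if u != "contra"][0])
        else:
            classes = tuple(uniq)
    neg, pos = classes
    Xn, Xp = X[labels == neg], X[labels == pos]
    if len(Xn) < 2 or len(Xp) < 2:
        raise ValueError("need at least 2 trials per class")
    center = X.mean(axis=0)
    Xc = X - center
    Sigma = Xc.T @ Xc / len(X)
    if gamma == 0.0 and np.linalg.cond(Sigma) > 1e10:
        warnings.warn("singular covariance; raising gamma floor to 1e-3")
        gamma = 1e-3
    Sigma_r = (1 - gamma) * Sigma + gamma * np.diag(np.diag(Sigma))
    d = Xn.mean(axis=0) - Xp.mean(axis=0)
    if delta == 0.0:
        l = np.linalg.solve(Sigma_r + 1e-12 * np.trace(Sigma_r) / len(d) * np.eye(len(d)), d)
    else:
        # scale delta relative to the Fisher problem's natural scale
        l = _sparse_discriminant(d, Sigma_r, delta)
        if not np.any(l):
            l = np.zeros(len(d))
            l[np.argmax(np.abs(d))] = np.sign(d[np.argmax(np.abs(d))])
    nrm = np.linalg.norm(l)
    l = l / nrm if nrm > 0 else l
    # sign convention: centered projections negative on the negative class
    s_neg = (Xn - center) @ l
    s_pos = (Xp - center) @ l
    if s_neg.mean() > s_pos.mean():
        l = -l
        s_neg, s_pos = -s_neg, -s_pos
    threshold = 0.5 * (s_neg.mean() + s_pos.mean())
    return DecoderModel(weights=l, gamma=gamma, delta=delta, center=center,
                        threshold=threshold, classes=(neg, pos),
                        feature_space=feature_space)


def tune_lda(X, labels, gammas=(0.0, 0.1, 0.3, 0.5, 0.9), deltas=(0.0, 0.01, 0.1, 1.0),
             folds: int = 5, seed: int = 0, **kwargs):
    """Grid search (gamma, delta) by CV validation error; ties resolve to the
    smallest delta, then the largest gamma.  Returns ``(decoder, gamma, delta)``
    with the decoder refit on all trials."""
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(gammas) == 0 or len(deltas) == 0:
        raise ValueError("empty grid")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(skf.split(X, labels))
    best = None
    for g in gammas:
        for dl in deltas:
            errs = []
            for tr, te in split:
                try:
                    dec = fit_sparse_lda(X[tr], labels[tr], gamma=g, delta=dl, **kwargs)
                except ValueError:
                    errs.append(1.0)
                    continue
                errs.append(np.mean(dec.predict(X[te]) != labels[te]))
            err = float(np.mean(errs))
            key = (err, dl, -g)
            if best is None or key < best[0]:
                best = (key, g, dl)
    _, g, dl = best
    return fit_sparse_lda(X, labels, gamma=g, delta=dl, **kwargs), g, dl


def project(decoder: DecoderModel, activity) -> np.ndarray | float:
    """Raw decoder projection s = l' r (linear, no offset)."""
    activity = np.asarray(activity, dtype=float)
    if activity.ndim == 1:
        if activity.shape[0] != decoder.weights.shape[0]:
            raise ValueError("dimension mismatch")
        return float(activity @ decoder.weights)
    if activity.shape[-1] != decoder.weights.shape[0]:
        raise ValueError("dimension mismatch")
    return activity @ decoder.weights


def window_average(features, bin_centers_s, at_ms: float = -300.0,
                   width_ms: float = 150.0):
    """Average (trials, T, F) features over bins whose centers fall in the
    window of ``width_ms`` centered ``at_ms`` relative to response onset."""
    t = np.asarray(bin_centers_s) * 1000.0
    mask = (t >= at_ms - width_ms / 2) & (t <= at_ms + width_ms / 2)
    if not mask.any():
        raise ValueError("window contains no bins of the grid")
    return np.asarray(features)[:, mask, :].mean(axis=1)


def trial_type_decodability(features, labels, bin_centers_s,
                            at_ms: float = -300.0, width_ms: float = 150.0,
                            folds: int = 10, gamma: float = 0.2,
                            delta: float = 0.0, seed: int = 0):
    """Cross-validated trial-type accuracy from window-averaged activity
    (a 150-ms window 300 ms before response onset by default).

    Returns ``(mean_accuracy, std_across_folds)``.  Works identically on
    FNS (neurons) or SAS (latent) features.
    """
    from sklearn.model_selection import StratifiedKFold

    Xw = window_average(features, bin_centers_s, at_ms=at_ms, width_ms=width_ms)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(Xw, labels):
        dec = fit_sparse_lda(Xw[tr], labels[tr], gamma=gamma, delta=delta)
        accs.append(np.mean(dec.predict(Xw[te]) == labels[te]))
    return float(np.mean(accs)), float(np.std(accs))


def rt_correlation(projections, reaction_times_ms, subset: str = "all"):
    """Spearman rank correlation of decoder projections with first-lick
    reaction time; ``subset='slow_gt_100ms'`` keeps RT > 100 ms trials.

    Returns ``(rho, p_value)``; ``(nan, nan)`` when undefined.
    """
    s = np.asarray(projections, dtype=float)
    rt = np.asarray(reaction_times_ms, dtype=float)
    ok = np.isfinite(rt) & np.isfinite(s)
    if subset == "slow_gt_100ms":
        ok &= rt > 100.0
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    s, rt = s[ok], rt[ok]
    if len(s) < 5:
        raise ValueError("need at least 5 trials with reaction times")
    if np.ptp(s) == 0 or np.ptp(rt) == 0:
        warnings.warn("constant projections or RTs; correlation undefined")
        return np.nan, np.nan
    rho, p = stats.spearmanr(s, rt)
    return float(rho), float(p)


def poly2_kernel(A, B=None):
    """(1 + <r_i r_j>)^2 with <.> the average over features."""
    A = np.atleast_2d(A)
    B = A if B is None else np.atleast_2d(B)
    return (1.0 + A @ B.T / A.shape[1]) ** 2


def _per_bin_cv(features, labels, fit_predict, folds, seed, balanced):
    from sklearn.metrics import balanced_accuracy_score
    from sklearn.model_selection import StratifiedKFold

    n, T, F = features.shape
    acc = np.empty(T)
    std = np.empty(T)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(skf.split(features[:, 0, :], labels))
    for t in range(T):
        fold_acc = []
        for tr, te in split:
            pred = fit_predict(features[tr, t], labels[tr], features[te, t])
            if balanced:
                fold_acc.append(balanced_accuracy_score(labels[te], pred))
            else:
                fold_acc.append(np.mean(pred == labels[te]))
        acc[t] = np.mean(fold_acc)
        std[t] = np.std(fold_acc)
    return acc, std


def correctness_decodability(features, correct_labels, bin_centers_s,
                             family: str = "SVM_poly2", folds: int = 10,
                             C: float = 1.0, seed: int = 0,
                             feature_space: str = "FNS") -> DecodabilityCurve:
    """Per-bin CV accuracy of correct-vs-error classification.

    ``features``: (trials, T, F) instantaneous activity; trial-type labels
    are never used.  ``family``: 'SVM_poly2' (the stated 2nd-order
    polynomial kernel) or 'QDA'.  Folds are stratified; when class imbalance
    exceeds 4:1 accuracy is reported balanced (flagged on the curve).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(correct_labels)
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() < 5:
        raise ValueError("need at least 5 trials in each correctness class")
    if counts.max() / counts.min() > 20:
        warnings.warn("extreme class imbalance (>20:1) in correctness labels")
    balanced = counts.max() / counts.min() > 4
    folds = min(folds, int(counts.min()))

    if family == "SVM_poly2":
        from sklearn.svm import SVC

        def fit_predict(Xtr, ytr, Xte):
            F = Xtr.shape[1]
            clf = SVC(kernel="poly", degree=2, coef0=1.0, gamma=1.0 / F, C=C)
            return clf.fit(Xtr, ytr).predict(Xte)
    elif family == "QDA":
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        def fit_predict(Xtr, ytr, Xte):
            clf = QuadraticDiscriminantAnalysis(reg_param=0.1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return clf.fit(Xtr, ytr).predict(Xte)
    else:
        raise ValueError(f"unknown decoder family {family!r}")

    acc, std = _per_bin_cv(features, labels, fit_predict, folds, seed, balanced)
    return DecodabilityCurve(accuracy=acc, std=std,
                             bin_centers_s=np.asarray(bin_centers_s),
                             family=family, label_type="correctness",
                             balanced=balanced)


def onset_time(curve: DecodabilityCurve, schedule, threshold: float = 0.65,
               min_run_bins: int | None = None):
    """Earliest time from which accuracy stays above threshold for at least
    one behavioral epoch's worth of bins (the session's shortest epoch by
    default).  Returns the bin-center time in seconds, or None."""
    if min_run_bins is None:
        min_run_bins = int(schedule.epoch_n_bins().min())
    above = curve.accuracy > threshold
    run_start, run_len = None, 0
    for t, a in enumerate(above):
        if a:
            if run_len == 0:
                run_start = t
            run_len += 1
            if run_len >= min_run_bins:
                return float(curve.bin_centers_s[run_start])
        else:
            run_len = 0
    return None


def previous_trial_decoding(features, prev_labels, bin_centers_s, presample_mask,
                            folds: int = 10, gamma: float = 0.2, delta: float = 0.0,
                            seed: int = 0, label_type: str = "prev_outcome"):
    """Decode a previous-trial variable from pre-sample activity.

    ``prev_labels`` entries equal to 'none' (no previous trial) are dropped.
    Returns ``(DecodabilityCurve over pre-sample bins, time_averaged_accuracy)``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(prev_labels)
    keep = labels != "none"
    features, labels = features[keep], labels[keep]
    presample_mask = np.asarray(presample_mask, dtype=bool)
    feats = features[:, presample_mask, :]
    centers = np.asarray(bin_centers_s)[presample_mask]
    counts = np.unique(labels, return_counts=True)[1]
    folds = min(folds, int(counts.min()))
    balanced = counts.max() / counts.min() > 4

    def fit_predict(Xtr, ytr, Xte):
        dec = fit_sparse_lda(Xtr, ytr, gamma=gamma, delta=delta)
        return dec.predict(Xte)

    acc, std = _per_bin_cv(feats, labels, fit_predict, folds, seed, balanced)
    curve = DecodabilityCurve(accuracy=acc, std=std, bin_centers_s=centers,
                              family="LDA", label_type=label_type,
                              balanced=balanced)
    return curve, float(acc.mean())


def decoder_similarity(decoders) -> np.ndarray:
    """Gram matrix l_t' l_t'' of unit-norm coding directions."""
    spaces = {d.feature_space for d in decoders}
    if len(spaces) > 1:
        raise ValueError("decoders come from mixed feature spaces")
    W = np.stack([d.weights for d in decoders])
    return W @ W.T
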