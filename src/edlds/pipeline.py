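"""End-to-end composition of the analysis flow.

These functions wire the pieces together the way the study runs them: screen
sessions, fit the state-space model on correct trials, cross-validate
leave-one-neuron-out variance explained against reference models, and run
the behavioral-prediction suite (trial-type decoding, reaction-time
correlation, rank statistics, correctness and previous-trial decoding) in
both the full neural space (FNS) and the model's shared activity space
(SAS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import decode, ranks
from .evaluate import (error_trial_generalization, lono_r2, psth_baseline_r2,
                       select_dim)
from .model import EDLDSParams, EpochSchedule, em_fit, infer_sas  # noqa: F401
from .session import SessionData

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "fit_session", "evaluate_model_variants",
           "analyze_session", "paired_signrank"]

MODEL_VARIANTS = ("edlds", "const_wmode", "const_wproj", "lds")


@dataclass
class FitResult:
    params: EDLDSParams
    trace: object
    schedule: EpochSchedule
    dim_selection: object | None = None


def _session_arrays(session: SessionData):
    tensor = session.binned
    if tensor is None:
        from .session import bin_session
        tensor = bin_session(session)
    Y = tensor.model_array()
    schedule = tensor.schedule()
    return tensor, Y, schedule


def paired_signrank(a, b) -> float:
    """Wilcoxon sign-rank p-value for paired session statistics (exact for
    n < 25, as in small-sample across-session comparisons)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    d = d[np.isfinite(d)]
    if len(d) < 5 or np.all(d == 0):
        return np.nan
    mode = "exact" if len(d) < 25 and not np.any(d == 0) else "auto"
    return float(stats.wilcoxon(d, mode=mode).pvalue)


def fit_session(session: SessionData, M="select", seed: int = 0,
                dims=None, variant: str = "edlds", folds: int = 10,
                **em_kwargs) -> FitResult:
    """Fit the model to a screened session's correct trials.

    ``M='select'`` runs cross-validated dimension selection over ``dims``
    (default 1..min(6, N-2)); an integer fixes the dimension.
    """
    tensor, Y, schedule = _session_arrays(session)
    mask = session.correct_mask() & ~session.early_lick_mask()
    Yc = Y[mask]
    labels = session.trial_types()[mask]
    dim_sel = None
    if M == "select":
        if dims is None:
            dims = range(1, min(6, session.n_units - 2) + 1)
        dim_sel = select_dim(Yc, schedule, dims, labels=labels, folds=folds,
                             seed=seed, **em_kwargs)
        M = dim_sel.selected
    params, trace = em_fit(Yc, schedule, int(M), seed=seed, variant=variant,
                           **em_kwargs)
    return FitResult(params=params, trace=trace, schedule=schedule,
                     dim_selection=dim_sel)


def evaluate_model_variants(Y, schedule, condition_labels, M: int,
                            seed: int = 0, folds: int = 2,
                            variants=MODEL_VARIANTS, **em_kwargs) -> dict:
    """Held-out LONO R^2 of the full model, its tied variants, and the PSTH
    reference on shared folds.

    ``Y``: correct-trial activity (n, T, N); ``condition_labels``: per-trial
    condition (trial type) used both for fold stratification and the PSTH.
    Returns ``{variant: R^2}`` including ``'psth'``.
    """
    from sklearn.model_selection import StratifiedKFold

    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(condition_labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(skf.split(Y, labels))
    out = {v: 0.0 for v in variants}
    out["psth"] = 0.0
    n_total = Y.shape[0]
    for tr, te in split:
        w = len(te) / n_total
        for v in variants:
            params, _ = em_fit(Y[tr], schedule, M, seed=seed, variant=v,
                               **em_kwargs)
            out[v] += w * lono_r2(params, schedule, Y[te]).r2
        out["psth"] += w * psth_baseline_r2(Y[tr], Y[te], labels[tr],
                                            labels[te]).r2
    return out


def _per_bin_projections(features, labels, train_mask, gamma=0.2, delta=0.0,
                         feature_space="FNS"):
    """Per-bin trial-type decoders (fit on training trials) and the centered
    projections of every trial.  Returns (projections (n, T), decoders)."""
    n, T, F = features.shape
    proj = np.empty((n, T))
    decoders = []
    for t in range(T):
        dec = decode.fit_sparse_lda(features[train_mask, t], labels[train_mask],
                                    gamma=gamma, delta=delta,
                                    feature_space=feature_space)
        proj[:, t] = dec.decision_value(features[:, t])
        decoders.append(dec)
    return proj, decoders


def analyze_session(session: SessionData, fit: FitResult, seed: int = 0,
                    forward_only: bool = False, gamma: float = 0.2,
                    delta: float = 0.0, include_shuffle: bool = True) -> dict:
    """The behavioral-prediction suite on one fitted session.

    Every statistic is computed twice — on the raw population activity (FNS)
    and on the inferred latent trajectories (SAS; smoothed by default,
    strictly causal with ``forward_only``).  Missing prerequisites (e.g. too
    few error trials) skip the corresponding entries with a logged reason.
    """
    rng = np.random.default_rng(seed)
    keep = ~session.early_lick_mask()
    sess = session.subset(keep) if not keep.all() else session
    tensor, Y, schedule = _session_arrays(sess)
    labels = sess.trial_types()
    correct = sess.correct_mask()
    mode = "forward_only" if forward_only else "smoothed"

    sas = infer_sas(fit.params, schedule, Y, mode=mode)
    spaces = {"fns": Y, "sas": sas}
    out = {"session_id": sess.session_id, "mode": mode,
           "n_units": sess.n_units, "n_trials": sess.n_trials,
           "latent_dim": fit.params.M}

    # --- trial-type decodability (correct trials, late delay window)
    for tag, feats in spaces.items():
        acc, sd = decode.trial_type_decodability(
            feats[correct], labels[correct], tensor.bin_centers_s,
            folds=10, gamma=gamma, delta=delta, seed=int(rng.integers(2**31)))
        out[f"tt_acc_{tag}"] = acc
        out[f"tt_acc_std_{tag}"] = sd

    # --- reaction-time correlation (dominant trial type, slow trials)
    rts = np.array([np.nan if t.reaction_time_ms is None else t.reaction_time_ms
                    for t in sess.trials])
    dom = "contra" if (labels[correct] == "contra").sum() >= (labels[correct] == "ipsi").sum() else "ipsi"
    rt_mask = correct & (labels == dom) & np.isfinite(rts)
    for tag, feats in spaces.items():
        try:
            Xw = decode.window_average(feats, tensor.bin_centers_s)
            dec = decode.fit_sparse_lda(Xw[correct], labels[correct],
                                        gamma=gamma, delta=delta)
            s = dec.decision_value(Xw[rt_mask])
            rho, p = decode.rt_correlation(s, rts[rt_mask], subset="slow_gt_100ms")
            out[f"rt_rho_{tag}"], out[f"rt_p_{tag}"] = rho, p
        except ValueError as e:
            logger.info("RT correlation skipped (%s): %s", tag, e)

    # --- rank statistics on per-bin decoder projections (correct trials)
    for tag, feats in spaces.items():
        proj, _ = _per_bin_projections(feats, labels, correct, gamma=gamma,
                                       delta=delta, feature_space=tag.upper())
        pc, lc = proj[correct], labels[correct]
        cons = ranks.epoch_rank_consistency(pc, schedule, lc)
        out[f"rank_epoch_{tag}"] = float(np.nanmean(list(cons.values())))
        try:
            lt = ranks.long_timescale_rank_corr(pc, lc, schedule)
            out[f"rank_longts_{tag}"] = float(np.nanmean(np.abs(list(lt.values()))))
        except ValueError as e:
            logger.info("long-timescale rank skipped (%s): %s", tag, e)
        pairs = ranks.adjacent_pair_stats(pc, lc, schedule)
        allp = np.concatenate([v for v in pairs.values() if len(v)]) if any(
            len(v) for v in pairs.values()) else np.array([])
        if len(allp):
            out[f"rank_pairs_{tag}"] = float(np.nanmean(allp))
        if tag == "sas":
            out["projections_sas"] = proj

    # --- neuron-shuffle control (rank continuity must drop).  Latents are
    # re-inferred from the shuffled tensor with the fitted model; shuffling
    # replaces the coherent population state with an N-fold-attenuated
    # mixture of other trials' states, so rank continuity falls.
    if include_shuffle:
        Vsh = ranks.shuffle_control(tensor.values, labels,
                                    seed=int(rng.integers(2**31)))
        Ysh = np.transpose(Vsh, (0, 2, 1))
        sas_sh = infer_sas(fit.params, schedule, Ysh, mode=mode)
        proj_sh, _ = _per_bin_projections(sas_sh, labels, correct, gamma=gamma,
                                          delta=delta, feature_space="SAS")
        cons_sh = ranks.epoch_rank_consistency(proj_sh[correct], schedule,
                                               labels[correct])
        out["rank_epoch_sas_shuffled"] = float(np.nanmean(list(cons_sh.values())))

    # --- previous-trial outcome decoding from pre-sample activity
    prev = np.array([t.prev_outcome for t in sess.trials])
    pre_mask = tensor.bin_epoch == "pre_sample"
    for tag, feats in spaces.items():
        lab = prev[prev != "none"]
        if len(np.unique(lab)) == 2 and min(np.unique(lab, return_counts=True)[1]) >= 5:
            _, acc = decode.previous_trial_decoding(
                feats, prev, tensor.bin_centers_s, pre_mask, folds=5,
                gamma=gamma, delta=delta, seed=int(rng.integers(2**31)))
            out[f"prev_acc_{tag}"] = acc
        else:
            logger.info("previous-trial decoding skipped (%s): class too small", tag)

    # --- correctness decoding and onset time
    n_err = int((~correct).sum())
    if n_err >= 5:
        corr_lab = np.where(correct, "correct", "error")
        for tag, feats in spaces.items():
            curve = decode.correctness_decodability(
                feats, corr_lab, tensor.bin_centers_s, family="SVM_poly2",
                folds=5, seed=int(rng.integers(2**31)), feature_space=tag.upper())
            onset = decode.onset_time(curve, schedule)
            out[f"correctness_curve_{tag}"] = curve
            out[f"correctness_onset_{tag}"] = onset
            out[f"correctness_late_delay_{tag}"] = float(
                curve.accuracy[schedule.bins_of(2)][-3:].mean())
        # reference-rank similarity of pooled projections
        sim = ranks.reference_rank_similarity(
            out["projections_sas"], correct, tensor.bin_centers_s,
            delay_onset_s=float(sess.epoch_times[0, 2]))
        out["refrank_correct_sas"] = sim["correct"]
        out["refrank_error_sas"] = sim["error"]
    else:
        logger.info("correctness decoding skipped: only %d error trials", n_err)

    # --- error-trial generalization of the correct-trial fit
    if n_err >= 1:
        conds = np.char.add(np.where(correct, "correct-", "error-"), labels)
        psth_err = psth_baseline_r2(Y, Y[~correct], conds, conds[~correct],
                                    r0=fit.params.r0, subset_tag="error")
        gen = error_trial_generalization(fit.params, schedule, Y[~correct],
                                         psth_reference_r2=psth_err.r2)
        out["r2_error"] = gen.get("r2_error")
        out["error_ratio_to_psth"] = gen.get("ratio_to_psth")
        out["r2_psth_error"] = psth_err.r2
    out.pop("projections_sas", None)
    return out
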