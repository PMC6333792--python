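"""Decode behavior from raw activity (FNS) versus the model's shared
activity space (SAS): trial type, reaction time, and previous-trial reward.

The SAS pools information across neurons and time through the fitted
dynamics, de-noising single trials; each decoder below is more accurate on
SAS features than on the raw population.
"""

import numpy as np

from edlds.decode import (fit_sparse_lda, previous_trial_decoding,
                          rt_correlation, trial_type_decodability,
                          window_average)
from edlds.model import infer_sas
from edlds.pipeline import fit_session
from edlds.simulate import SimConfig, generate_session

cfg = SimConfig(seed=1, n_units_range=(12, 12), n_trials=150)
session, truth = generate_session(cfg, session_seed=42)
fit = fit_session(session, M=4, seed=0, max_iter=50, tol=1e-5)

tensor = session.binned
Y = tensor.model_array()
sas = infer_sas(fit.params, tensor.schedule(), Y)          # (trials, T, M)
labels = session.trial_types()
correct = session.correct_mask() & ~session.early_lick_mask()

print("trial-type decodability (150-ms window, 300 ms before response):")
for tag, feats in (("FNS", Y), ("SAS", sas)):
    acc, sd = trial_type_decodability(feats[correct], labels[correct],
                                      tensor.bin_centers_s, folds=10, seed=0)
    print(f"  {tag}: {acc:.3f} +/- {sd:.3f}")

rts = np.array([np.nan if t.reaction_time_ms is None else t.reaction_time_ms
                for t in session.trials])
dom = "ipsi"
mask = correct & (labels == dom) & np.isfinite(rts)
print(f"\nreaction-time Spearman correlation ({dom} trials, RT > 100 ms):")
for tag, feats in (("FNS", Y), ("SAS", sas)):
    Xw = window_average(feats, tensor.bin_centers_s)
    dec = fit_sparse_lda(Xw[correct], labels[correct], gamma=0.2)
    rho, p = rt_correlation(dec.decision_value(Xw[mask]), rts[mask],
                            subset="slow_gt_100ms")
    print(f"  {tag}: rho = {rho:+.2f} (p = {p:.3f})")

prev = np.array([t.prev_outcome for t in session.trials])
pre = tensor.bin_epoch == "pre_sample"
print("\nprevious-trial reward decoded from pre-sample activity:")
for tag, feats in (("FNS", Y), ("SAS", sas)):
    _, acc = previous_trial_decoding(feats, prev, tensor.bin_centers_s, pre,
                                     folds=5, seed=0)
    print(f"  {tag}: accuracy {acc:.3f} (chance 0.5)")
print("\nNegative rho means stronger choice coding -> faster licks; the")
print("pre-sample reward trace is a slow internal state only visible after")
print("the model's de-noising.")
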