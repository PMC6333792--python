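"""Error trials under a correct-trial model: the dynamics fitted on correct
trials also explain error-trial activity, and trial correctness becomes
decodable from the latent state well before the response.
"""

import numpy as np

from edlds.decode import correctness_decodability, onset_time
from edlds.evaluate import error_trial_generalization, psth_baseline_r2
from edlds.model import infer_sas
from edlds.pipeline import fit_session
from edlds.simulate import SimConfig, generate_session

cfg = SimConfig(seed=1, n_units_range=(12, 12), n_trials=200)
session, _ = generate_session(cfg, session_seed=43)
tensor = session.binned
sched = tensor.schedule()
Y = tensor.model_array()
labels = session.trial_types()
correct = session.correct_mask() & ~session.early_lick_mask()
errors = ~session.correct_mask() & ~session.early_lick_mask()
print(f"{correct.sum()} correct, {errors.sum()} error trials")

fit = fit_session(session, M=4, seed=0, max_iter=50, tol=1e-5)

conds = np.char.add(np.where(session.correct_mask(), "correct-", "error-"),
                    labels)
psth = psth_baseline_r2(Y, Y[errors], conds, conds[errors], r0=fit.params.r0)
gen = error_trial_generalization(fit.params, sched, Y[errors],
                                 psth_reference_r2=psth.r2)
print(f"\nerror-trial LONO R^2 (correct-trial model): {gen['r2_error']:.3f}")
print(f"fraction of the PSTH-reference explained variance: "
      f"{100 * gen['ratio_to_psth']:.0f}%")

sas = infer_sas(fit.params, sched, Y)
corr_lab = np.where(session.correct_mask(), "correct", "error")
keep = ~session.early_lick_mask()
print("\ncorrectness decoding (trial type never used):")
for tag, feats in (("FNS", Y), ("SAS", sas)):
    curve = correctness_decodability(feats[keep], corr_lab[keep],
                                     tensor.bin_centers_s, folds=5, seed=0)
    onset = onset_time(curve, sched)
    late = curve.accuracy[sched.bins_of(2)][-3:].mean()
    print(f"  {tag}: late-delay accuracy {late:.2f}, onset "
          f"{'not reached' if onset is None else f'{onset:+.2f} s'}")
print("\nOnset is the first time accuracy stays above 0.65 for a full")
print("epoch; in the latent space errors announce themselves during the")
print("delay, long before the lick.")
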