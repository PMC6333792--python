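"""Single-trial rank structure: trials keep their relative position (rank)
in the population code across behavioral epochs and across neighboring
trials, and a neuron-shuffle control destroys it.

Projections of each trial onto per-bin trial-type decoders are converted
to ranks (1 = largest); the statistics quantify rank persistence.
"""

import numpy as np

from edlds.model import infer_sas
from edlds.pipeline import _per_bin_projections, fit_session
from edlds.ranks import (adjacent_pair_stats, epoch_rank_consistency,
                         long_timescale_rank_corr, rank_transform,
                         shuffle_control)
from edlds.simulate import SimConfig, generate_session

cfg = SimConfig(seed=1, n_units_range=(12, 12), n_trials=150)
session, _ = generate_session(cfg, session_seed=42)
fit = fit_session(session, M=4, seed=0, max_iter=50, tol=1e-5)

tensor = session.binned
sched = tensor.schedule()
Y = tensor.model_array()
sas = infer_sas(fit.params, sched, Y)
labels = session.trial_types()
correct = session.correct_mask() & ~session.early_lick_mask()

print("worked example: projections (0.5, 1.3, 0.2) ->",
      rank_transform(np.array([[0.5], [1.3], [0.2]]), "pooled")
      ["pooled"].ranks[:, 0], "(rank 1 = largest)")

for tag, feats in (("FNS", Y), ("SAS", sas)):
    proj, _ = _per_bin_projections(feats, labels, correct)
    cons = epoch_rank_consistency(proj[correct], sched, labels[correct])
    lt = long_timescale_rank_corr(proj[correct], labels[correct], sched)
    pairs = adjacent_pair_stats(proj[correct], labels[correct], sched)
    allp = np.concatenate([v for v in pairs.values() if len(v)])
    print(f"\n{tag}:")
    print(f"  adjacent-epoch rank consistency (Spearman): "
          f"{np.nanmean(list(cons.values())):.3f}")
    print(f"  trial-order rank correlation:               "
          f"{np.nanmean(np.abs(list(lt.values()))):.3f}")
    print(f"  neighboring-pair rank-dynamics consistency: "
          f"{np.nanmean(allp):.3f}")

# control: per-neuron trial shuffle within type, latents re-inferred
Vs = shuffle_control(tensor.values, labels, seed=1)
sas_sh = infer_sas(fit.params, sched, np.transpose(Vs, (0, 2, 1)))
proj_sh, _ = _per_bin_projections(sas_sh, labels, correct)
cons_sh = epoch_rank_consistency(proj_sh[correct], sched, labels[correct])
print(f"\nSAS consistency after neuron-shuffle control: "
      f"{np.nanmean(list(cons_sh.values())):.3f}")
print("Shuffling preserves every neuron's PSTH exactly but replaces the")
print("coherent population state with a mixture, reducing rank continuity.")
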