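# edlds — event-dependent linear dynamical systems for neural populations

`edlds` models simultaneously recorded neural populations during
trial-based behavior with a latent linear dynamical system whose
parameters switch at cued task events. It is built for delayed
two-alternative tasks (sample → delay → response epochs, as in mouse
anterior lateral motor cortex recordings), where population dynamics
change sharply at epoch boundaries but are well approximated as linear
within an epoch. The intended users are systems neuroscientists analyzing
trial-based electrophysiology who want single-trial latent trajectories
and the behavioral predictions they support.

## The model

Binned population activity `r(t) ∈ R^N` (firing rates, 67-ms bins) is a
noisy linear readout of a low-dimensional latent state `x(t) ∈ R^M`,
whose dynamics and readout both depend on the current behavioral epoch
`s(t)`:

    x(t) = W_mode(s) x(t−1) + w(t−1),   w ~ N(0, diag q_int(s))
    r(t) = W_proj(s) x(t) + r0 + v(t),  v ~ N(0, diag q_ext(s))

Because switch times are cued by the task, inference is exact (Kalman
filter/smoother) and fitting is plain EM with epoch-partitioned updates —
no combinatorial switching posterior. The latent space (the *shared
activity space*, SAS) de-noises single trials by pooling across neurons
and time; the package's analysis suite quantifies what that buys:

- **Model evaluation** — leave-one-neuron-out (LONO) cross-validated
  variance explained; latent-dimension selection; tied-parameter ablations
  (constant dynamics, constant emission, both) and a PSTH reference model;
  generalization of correct-trial fits to error trials.
- **Decoding** — per-bin sparse linear-discriminant trial-type decoders
  with unit-norm weights and a fixed sign convention; reaction-time rank
  correlations; correctness decoding (polynomial-kernel SVM / QDA) and its
  onset time; previous-trial outcome decoding from pre-sample activity.
- **Rank structure** — single-trial rank transforms of decoder
  projections and the consistency statistics that expose slow internal
  states: adjacent-epoch rank consistency, trial-order (long-timescale)
  rank correlation, neighboring-pair rank-dynamics consistency,
  reference-rank similarity for error trials, and the neuron-shuffle
  control that conserves PSTHs while destroying population coupling.
- **Synthetic sessions** — a ground-truth generator that emulates the
  statistical structure of the recordings (epoch-switched dynamics,
  trial-type coding, slow across-trial drift, reward-history shifts,
  state-coupled reaction times, attenuate-and-flip error trials), so the
  entire pipeline is testable without any data download.

## Worked example

```
$ python examples/01_fit_and_evaluate.py
session: 12 units, 150 trials, 27 errors
EM converged in 23 iterations, final log-likelihood -235689.1

held-out LONO R^2 (higher = better single-trial prediction):
  edlds        0.0971
  const_wmode  0.0961
  const_wproj  0.0861
  lds          0.0860
  psth         0.0178
```

The full epoch-switched model predicts held-out neurons best; tying the
emission matrices across epochs (`const_wproj`) costs more than tying the
dynamics (`const_wmode`), and the trial-averaged PSTH reference explains
far less because it cannot track trial-specific latent states. The other
examples print decoding contrasts between raw activity and the latent
space (`02_decoding_behavior.py`), single-trial rank structure and the
shuffle control (`03_rank_structure.py`), and error-trial analyses
(`04_error_trials.py`).

A thin CLI wraps the same pipeline for batch use:

```
edlds simulate --seed 1 --out runs/sessions
edlds fit --sessions runs/sessions --out runs/models --dim 4
edlds analyze --sessions runs/sessions --models runs/models --out runs/reports
```

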