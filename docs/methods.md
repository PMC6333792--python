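# Methods

## Model

The package implements an event-dependent linear dynamical system (EDLDS):
a linear-Gaussian state-space model of binned neural population activity
whose parameters switch at externally cued event times. For a trial with
bins `t = 1..T`, each bin belonging to a behavioral epoch
`s(t) ∈ {pre-sample, sample, delay, response}`:

    x(t) = W_mode(s) x(t−1) + w(t−1),     w ~ N(0, diag q_int(s))
    r(t) = W_proj(s) x(t) + r0 + v(t),    v ~ N(0, diag q_ext(s))
    x(1) ~ N(x0, Q0)

`r(t) ∈ R^N` is the observed firing-rate vector (the full neural space,
FNS); `x(t) ∈ R^M`, `M < N`, is the latent state (the shared activity
space, SAS). `W_mode` is the latent dynamics, `W_proj` the emission,
`q_int` the latent innovation variances (inputs from unrecorded areas),
`q_ext` per-neuron residual variances, and `r0` a fixed per-neuron offset.
Within an epoch the model is a stationary LDS; all switching times are
known from the task, so inference stays exactly Gaussian — the model's key
simplification relative to switching-LDS models with inferred switch times
(which are out of scope here, along with GPFA-style baselines).

### Epoch boundary convention

Epoch `s` owns bins `t(s−1)+1 .. t(s)` (the first epoch also owns bin 1)
for emissions, and owns the transitions *into* its bins: the step from the
last bin of epoch `s` into the first bin of epoch `s+1` uses
`W_mode(s+1)`. This tiles both bins and transitions exactly once.
M-step normalizers equal the number of summed terms.

## Inference and estimation

Filtering is the standard Kalman forward pass with epoch-indexed matrices;
smoothing is the RTS backward pass, which also yields the lag-one
cross-covariances the M-step needs. Because all trials share one bin grid
and one parameter set, the covariance recursions are data-independent and
computed once per session; only the means are per-trial, so a whole
session is filtered with `T` small matrix operations regardless of trial
count. The exact marginal log-likelihood comes from the prediction-error
decomposition. Correctness is pinned by a brute-force oracle: on random
small instances, the filter/smoother output is compared at `1e−8` to
conditioning the dense joint Gaussian of all latents and observations.

Estimation is EM. The E-step smooths every trial; the M-step solves the
epoch-partitioned regression updates (emissions from `E[x_t x_t']` and
`E[x_t r̄_t']` summed over the epoch's bins; dynamics from lag-one moments
summed over the epoch's transitions), projects both noise covariances to
their diagonal, and updates `x0, Q0` from pooled first-bin posteriors.
`r0` is held at the per-neuron training mean throughout (the model defines
centered observations without an update rule for the offset, and freezing
it keeps the likelihood well-defined). `x0, Q0` are shared across trial
types by default. With diagonal noise the row-wise least-squares update is
the exact constrained M-step, so the log-likelihood is non-decreasing;
every fit asserts this at relative tolerance `1e−6`. With a single epoch
the updates collapse to textbook LDS EM, verified against an independently
coded per-trial implementation.

Tied variants (`lds`, `const_wmode`, `const_wproj`) pool the corresponding
M-step sums across epochs; they are reference models for the ablation
comparison, fitted on shared folds.

Numerical choices: variance floors at `1e−6 ×` data variance
(observations) and `1e−6` (latents, whose scale is ~1 after
factor-analysis initialization); ridge jitter `1e−8` on moment inversions;
Joseph-form covariance updates and symmetrization everywhere; convergence
at relative log-likelihood change `1e−6` (tests and the acceptance script
use `1e−4`–`1e−5` with capped iterations — problem sizes chosen so every
result is stable at those settings). Initialization: factor analysis on
pooled centered data for the emission, `0.9·I` dynamics, unit-ish noise;
seed-controlled. Degenerate (near-constant) input floors variances and
flags non-convergence instead of crashing.

### Identifiability

The latent basis is arbitrary: `x → Gx`, `W_proj → W_proj G⁻¹` leaves the
likelihood unchanged, so `W_mode` and `q_int` are recoverable only up to
that reparameterization. Recovery tests therefore score the emission
*subspace* (principal angles) and the observation-noise variances; latent
innovation variances are not compared in absolute terms.

## Evaluation

Goodness of fit is leave-one-neuron-out (LONO) variance explained: on test
trials, neuron `i`'s activity is removed, latents are inferred from the
remaining neurons, and `r̂_i(t) = W_proj_i(s) x_t + r0_i` is scored as

    R² = 1 − ⟨ ⟨(r_i − r̂_i)²⟩_{t,trials} / ⟨(r_i − r0_i)²⟩_{t,trials} ⟩_i

with the denominator deviating from the per-neuron training mean. The
mean-activity (PSTH) reference predicts each neuron by its training-set
condition mean (correct/error × contra/ipsi) and is scored by the same
formula. Latent dimension is selected by 10-fold cross-validated LONO over
candidate dimensions, taking the smallest dimension within 10% of the best
`R²` (on the signed scale: the threshold is `max − 0.1·|max|`, which
reduces to `0.9·max` for positive values). Error-trial generalization
evaluates correct-trial parameters on error trials and reports the ratio
of the model's explained variance to the PSTH reference's.

## Decoding

Trial-type decoders are sparse linear discriminants per time bin: the
Fisher discriminant with sample covariance shrunk toward its diagonal
(`Σ_r = (1−γ)Σ + γ diag Σ`, `γ ∈ [0,1]`) and an L1 penalty `Δ`. The
printed ratio-plus-L1 objective is scale-degenerate (the discriminant
ratio is scale-invariant, the penalty is not), so the optimizer solves the
equivalent penalized form `½ lᵀΣ_r l − dᵀl + Δ|l|₁` by coordinate descent
and L2-normalizes; `Δ = 0` reproduces the closed-form Fisher direction
exactly and large `Δ` keeps the single most discriminative feature. The
sign convention makes centered contra-trial projections negative.
`(γ, Δ)` can be tuned by grid cross-validation (ties resolve to the
smallest `Δ`, then the largest `γ`).

Decodability statistics follow the study design: trial type from a 150-ms
window centered 300 ms before response onset (10-fold CV); reaction time
as the Spearman correlation between window projections and first-lick
latency, with a slow-trial (>100 ms) subset; correctness (never using
trial type) per 67-ms bin with a 2nd-order polynomial-kernel SVM,
`G(r_i, r_j) = (1 + ⟨r_i r_j⟩)²` (implemented as sklearn's poly kernel
with `coef0 = 1`, `gamma = 1/N`, `C = 1`), or QDA; correctness onset as
the first bin from which accuracy stays above 0.65 contiguously for at
least the session's shortest epoch (the most conservative reading of "at
least one behavioral epoch"; run length configurable). Stratified folds
throughout; accuracy is balanced when class imbalance exceeds 4:1.
Previous-trial variables (reward, choice, stimulus, early lick) are
decoded from pre-sample bins, first trial excluded.

## Rank statistics

Per-bin decoder projections are converted to relative ranks across trials
(rank 1 = largest, ties averaged), within trial type or pooled. The
statistics: Spearman consistency of epoch-averaged projections between
adjacent epochs; Pearson correlation of trial ordinal position with
epoch-averaged rank (long-timescale order); rank-dynamics consistency of
two trials' within-epoch rank time-courses, implemented as printed with an
absolute-value numerator (`|Pearson|` on ranks — note this statistic has a
positive null mean, which is why a signed variant and permutation nulls
are provided); neighboring-pair statistics over consecutive same-type
trials; and similarity of instantaneous pooled ranks to the late-sample
reference window (−300–0 ms before delay onset), split by correctness.

The neuron-shuffle control replaces each neuron's single-trial activity by
the same neuron's activity on another trial of the same type (independent
permutations per neuron). This conserves every per-neuron, per-type PSTH
exactly while destroying within-trial cross-neuron coupling. Downstream
rank statistics are recomputed by re-inferring latents from the shuffled
tensor with the model fitted on the original data. Refitting EM on
shuffled data is deliberately not used for this control: with the
cross-neuron covariance destroyed, a refit collapses the posterior onto
the smooth dynamics prior, and since rank consistency is scale-free, the
over-smoothed latents inflate the statistic instead of dropping it.

## Synthetic sessions

The generator emulates the regime of simultaneous frontal-cortex
recordings in the delayed two-alternative task: 6–31 units, 200 trials,
~15% errors, ~4% early licks, four epochs (pole task: 1.3 s sample,
1.3 s delay; sound task: 1.15 s / 2.0 s; pre-sample and response analysis
windows of 0.8 s and 1.0 s), 67-ms bins anchored at the go cue.

Ground truth is a structured parameter draw plus planted behavioral
couplings superimposed on the latent mean path:

- **Epoch structure.** Per-epoch time constants (0.08, 0.2, 0.6, 0.25 s:
  longest in the delay, shortest pre-sample) with planar rotations
  (4, 8, 30, 12°) in the dynamics, and an emission basis rotated across
  epochs (0, 12, 20, 45° — the largest switch into the response epoch).
- **Trial-type coding** of magnitude 2.0 along one latent direction,
  ramping over the sample and held through the delay.
- **Across-trial drift**: an AR(1) per-trial latent offset (ρ = 0.95,
  scale 0.8) constant within trial — the source of rank continuity,
  neighboring-pair similarity and trial-order structure.
- **History effect**: a pre-sample latent shift (0.8) on trials following
  a rewarded trial, fading over the sample.
- **Reaction times**: a mixture of fast responses (100 ± 3 ms, insensitive
  to the neural state) and slow responses (200–600 ms) whose Spearman
  correlation with the late-delay coding amplitude is planted at −0.5 via
  a Gaussian copula, separately within correct and within error trials
  (error-trial evidence is systematically shifted, and RT analyses run on
  correct trials, so the link must hold within-group to be recoverable).
- **Error trials**: the type-coding component attenuates and flips
  (to −0.6×) at a random time in the first 40% of the delay, accompanied
  by an orthogonal "error-state" latent offset (3.0) — so correctness is
  decodable without knowledge of trial type. An alternative
  "unrelated-dynamics" mechanism serves as a negative control.
- **Observation noise** of variance ~9 (spike rates in these bins are
  noisy; single-bin single-neuron SNR is well below 1, which is what makes
  the latent space's de-noising visible).

Defaults were calibrated, before the acceptance suite was frozen, so the
generated sessions reproduce the reported phenomenology of the recordings
(trial-type decodability ≈ 0.85 raw / 0.95 latent; long-timescale rank
correlation ≈ 0.2; error-trial variance ratio ≈ 0.5–0.9; correctness
decodable early in the latent space only). Gaussian rate observations are
the default (matching the model); Poisson emission and count quantization
exist as robustness options, off by default.

What the generator does **not** emulate: spiking point-process statistics
(refractoriness, bursting), non-stationary firing-rate drift within
epochs beyond the linear dynamics, cell-type structure, correlated
observation noise, and real epoch-boundary jitter. Passing tests
demonstrate that the pipeline recovers structure *of the kind the model
assumes*; they do not certify performance on real recordings.

## Problem sizes in tests and the acceptance script

The test suite runs the full benchmark at 20 sessions (units 6–31,
200 trials); parameter recovery uses 20 neurons / 3 latents / 200 trials
with dimension search over 1–5 at 10 folds; the acceptance script uses
10 sessions. EM runs with `max_iter` 25–100 and tolerances `1e−4`–`1e−6`
depending on stage; all reported contrasts are stable under these
settings.

## Known limitations

- `q_int`/`W_mode` comparisons across fits require subspace alignment
  (see Identifiability); the package does not provide an automatic
  alignment utility.
- The sparse-LDA coordinate descent is exact for the penalized form but
  is not guaranteed to find the global optimum of the nonconvex printed
  ratio objective for large `Δ`; in practice the two agree in the regimes
  tested.
- The forward-only (strictly causal) mode uses the same fitted parameters
  as the smoothed mode; it is a control for inference non-causality, not
  an online estimator with causal parameter updates.
- Session screening and binning assume the fixed task epoch durations;
  variable epoch timing across trials is not supported.
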