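"""Synthetic delayed-response sessions with ground truth.

The generator emulates the statistical structure the downstream analyses
assume in real ALM recordings: an epoch-switched low-dimensional latent
process read out by many noisy neurons, a trial-type coding direction that
ramps up during the sample epoch, a slow AR(1) across-trial latent offset
(rank continuity and long-timescale order), a pre-sample shift that tracks
the previous trial's reward, reaction times coupled to the late-delay
coding amplitude (with a fast-response mixture insensitive to it), and
error trials whose type-coding component attenuates and flips at a random
time after the sample epoch.  All randomness flows from the configured
seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .model import EDLDSParams, EpochSchedule, sample_trials, EPOCH_NAMES
from .session import (BinnedTensor, SessionData, Task, TrialMeta, TrialType,
                      UnitMeta, TASK_EPOCH_DURATIONS, _bin_grid)

__all__ = ["SimConfig", "GroundTruth", "random_params", "default_schedule",
           "generate_session", "generate_benchmark"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for synthetic sessions.

    Defaults mirror the recorded sessions' regime: 6-31 simultaneous units,
    four epochs with the longest time constant in the delay and the shortest
    in the pre-sample, two trial types, ~15% error trials, slow across-trial
    drift, reaction times coupled to the latent state.
    """

    seed: int
    task: str = "pole"
    n_sessions: int = 20
    n_units_range: tuple = (6, 31)
    n_trials: int = 200
    error_rate: float = 0.15
    early_lick_rate: float = 0.04
    latent_dim: int = 4
    bin_width_ms: float = 67.0
    # per-epoch latent time constants (s): pre-sample, sample, delay, response
    epoch_taus_s: tuple = (0.08, 0.2, 0.6, 0.25)
    # per-epoch rotation (deg) of the emission subspace away from the base
    emission_rotation_deg: tuple = (0.0, 12.0, 20.0, 45.0)
    # per-epoch planar rotation (deg) inside the latent dynamics
    mode_rotation_deg: tuple = (4.0, 8.0, 30.0, 12.0)
    coding_magnitude: float = 2.0
    obs_noise: float = 9.0
    drift_rho: float = 0.95
    drift_scale: float = 0.8
    rt_spearman: float = 0.5          # planted |rho| between evidence and slow RT
    fast_fraction: float = 0.3
    fast_mean_ms: float = 100.0
    fast_sd_ms: float = 3.0
    slow_rt_range_ms: tuple = (200.0, 600.0)
    history_effect: float = 0.8
    error_mechanism: str = "flip"     # 'flip' | 'unrelated'
    error_flip_attenuation: float = 0.6
    # orthogonal latent shift marking the error state after the flip time
    error_state_offset: float = 3.0
    quantize_counts: bool = False
    poisson: bool = False

    def __post_init__(self):
        lo, hi = self.n_units_range
        if not (2 <= lo <= hi):
            raise ValueError("invalid n_units_range")
        if not (0 <= self.error_rate < 1 and 0 <= self.early_lick_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.error_mechanism not in ("flip", "unrelated"):
            raise ValueError(f"unknown error mechanism {self.error_mechanism!r}")
        if not 0 <= self.rt_spearman < 1:
            raise ValueError("rt_spearman must be in [0, 1)")


@dataclass
class GroundTruth:
    params: EDLDSParams
    latents: np.ndarray               # (trials, T, M) true latent paths
    latent_offsets: np.ndarray        # (trials, M) AR(1) per-trial offsets
    coding_dir: np.ndarray            # latent-space trial-type direction
    history_dir: np.ndarray
    rt_spearman: float
    history_effect: float
    error_mechanism: str
    error_flip_times_s: dict          # trial index -> flip onset (s)


def default_schedule(task: str = "pole", bin_width_ms: float = 67.0) -> EpochSchedule:
    dur = TASK_EPOCH_DURATIONS[Task(task)]
    return EpochSchedule.from_durations([dur[e] for e in EPOCH_NAMES],
                                        bin_width_ms / 1000.0)


def _planar_rotation(M, angle_rad):
    R = np.eye(M)
    for a in range(0, M - 1, 2):
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        R[a, a], R[a, a + 1], R[a + 1, a], R[a + 1, a + 1] = c, -s, s, c
    return R


def random_params(N: int, M: int, schedule: EpochSchedule, rng,
                  epoch_taus_s=(0.08, 0.2, 0.6, 0.25),
                  emission_rotation_deg=(0.0, 12.0, 20.0, 45.0),
                  mode_rotation_deg=(4.0, 8.0, 30.0, 12.0),
                  obs_noise: float = 1.5,
                  bin_width_s: float = 0.067) -> EDLDSParams:
    """Draw a structured parameter set: per-epoch decay from the epoch time
    constants, mild planar rotations in the dynamics, and an emission basis
    rotated across epochs (strongest switch into the response epoch)."""
    S = schedule.n_epochs
    a = np.exp(-bin_width_s / np.asarray(epoch_taus_s[:S]))
    W_mode = np.stack([a[s] * _planar_rotation(M, np.deg2rad(mode_rotation_deg[s]))
                       for s in range(S)])
    q_int = np.stack([np.full(M, max(1.0 - a[s] ** 2, 1e-3)) for s in range(S)])
    base = np.linalg.qr(rng.standard_normal((N, M)))[0]
    # complement directions, orthogonal to the base column space
    comp = rng.standard_normal((N, M))
    comp -= base @ (base.T @ comp)
    comp = np.linalg.qr(comp)[0]
    scale = np.sqrt(0.8 * N / M)
    W_proj = np.empty((S, N, M))
    for s in range(S):
        phi = np.deg2rad(emission_rotation_deg[s])
        W_proj[s] = scale * (np.cos(phi) * base + np.sin(phi) * comp)
    q_ext = np.stack([obs_noise * rng.uniform(0.6, 1.4, size=N) for _ in range(S)])
    r0 = rng.uniform(2.0, 10.0, size=N)
    return EDLDSParams(W_mode=W_mode, W_proj=W_proj, q_int=q_int, q_ext=q_ext,
                       x0=np.zeros(M), Q0=0.5 * np.eye(M), r0=r0)


def _ramp_profile(schedule: EpochSchedule) -> np.ndarray:
    """Type-coding envelope: 0 pre-sample, linear rise over sample, held
    through delay, mild further rise in response."""
    T = schedule.n_bins
    prof = np.zeros(T)
    sample = schedule.bins_of(1)
    prof[sample] = np.linspace(0, 1, len(sample), endpoint=True)
    prof[schedule.bins_of(2)] = 1.0
    resp = schedule.bins_of(3)
    prof[resp] = np.linspace(1.0, 1.3, len(resp))
    return prof


def _presample_profile(schedule: EpochSchedule) -> np.ndarray:
    """History envelope: 1 over pre-sample, fading to 0 across the sample."""
    T = schedule.n_bins
    prof = np.zeros(T)
    prof[schedule.bins_of(0)] = 1.0
    sample = schedule.bins_of(1)
    prof[sample] = np.linspace(1.0, 0.0, len(sample), endpoint=True)
    return prof


def generate_session(config: SimConfig, session_seed: int,
                     session_id: str | None = None):
    """One synthetic session plus its ground truth.

    Deterministic in ``(config, session_seed)``.
    """
    rng = np.random.default_rng(session_seed)
    task = Task(config.task)
    schedule = default_schedule(config.task, config.bin_width_ms)
    T, M = schedule.n_bins, config.latent_dim
    n = config.n_trials
    lo, hi = config.n_units_range
    N = int(rng.integers(lo, hi + 1))
    bw_s = config.bin_width_ms / 1000.0

    params = random_params(N, M, schedule, rng,
                           epoch_taus_s=config.epoch_taus_s,
                           emission_rotation_deg=config.emission_rotation_deg,
                           mode_rotation_deg=config.mode_rotation_deg,
                           obs_noise=config.obs_noise, bin_width_s=bw_s)

    coding_dir = np.zeros(M); coding_dir[0] = 1.0
    history_dir = np.zeros(M); history_dir[M - 1] = 1.0

    type_sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)   # -1 contra, +1 ipsi
    is_error = rng.random(n) < config.error_rate
    is_early = rng.random(n) < config.early_lick_rate
    # trial correctness: error trials are incorrect
    correct = ~is_error

    # previous-trial reward (first trial has none)
    prev_rewarded = np.zeros(n, dtype=bool)
    prev_rewarded[1:] = correct[:-1] & ~is_early[:-1]

    # AR(1) across-trial latent offsets
    offsets = np.zeros((n, M))
    if config.drift_scale > 0:
        offsets[0] = config.drift_scale * rng.standard_normal(M)
        innov_sd = config.drift_scale * np.sqrt(1 - config.drift_rho ** 2)
        for i in range(1, n):
            offsets[i] = (config.drift_rho * offsets[i - 1]
                          + innov_sd * rng.standard_normal(M))

    ramp = _ramp_profile(schedule)
    pre_prof = _presample_profile(schedule)
    delay_bins = schedule.bins_of(2)
    dur = TASK_EPOCH_DURATIONS[task]
    delay_onset_s = -dur["delay"]

    # per-trial coding envelope (errors attenuate-then-flip after sample end)
    flip_times = {}
    coding_coef = np.empty((n, T))
    error_state = np.zeros((n, T))
    centers = _bin_grid(task, config.bin_width_ms)[2]
    for i in range(n):
        coef = type_sign[i] * config.coding_magnitude * ramp
        if is_error[i] and config.error_mechanism == "flip":
            t_flip = float(rng.uniform(delay_onset_s,
                                       delay_onset_s + 0.4 * dur["delay"]))
            flip_times[i] = t_flip
            blend = np.clip((centers - t_flip) / 0.33, 0.0, 1.0)
            target = -type_sign[i] * config.error_flip_attenuation * config.coding_magnitude
            coef = (1 - blend) * coef + blend * target * ramp
            error_state[i] = config.error_state_offset * blend
        coding_coef[i] = coef

    error_dir = np.zeros(M)
    if M > 1:
        error_dir[1] = 1.0
    latent_means = (coding_coef[:, :, None] * coding_dir
                    + error_state[:, :, None] * error_dir
                    + (config.history_effect * prev_rewarded[:, None]
                       * pre_prof[None, :])[:, :, None] * history_dir)

    Y, X = sample_trials(params, schedule, n, seed=rng.integers(2 ** 31),
                         latent_offsets=offsets, latent_means=latent_means)

    if is_error.any() and config.error_mechanism == "unrelated":
        other = random_params(N, M, schedule, np.random.default_rng(rng.integers(2 ** 31)),
                              obs_noise=config.obs_noise, bin_width_s=bw_s)
        idx = np.flatnonzero(is_error)
        Y_err, X_err = sample_trials(other, schedule, len(idx),
                                     seed=rng.integers(2 ** 31))
        Y[idx], X[idx] = Y_err, X_err

    if config.poisson:
        lam = np.clip(Y, 0.0, None) * bw_s
        Y = rng.poisson(lam) / bw_s
    elif config.quantize_counts:
        Y = np.round(np.clip(Y, 0.0, None) * bw_s) / bw_s

    # reaction times from late-delay coding amplitude (true latents)
    evidence = type_sign * (X[:, delay_bins[-5:], :] @ coding_dir).mean(axis=1)
    rt = np.full(n, np.nan)
    fast = rng.random(n) < config.fast_fraction
    rt[fast] = rng.normal(config.fast_mean_ms, config.fast_sd_ms, size=fast.sum())
    slow = ~fast
    # the RT link is planted separately within correct and error trials:
    # error-trial evidence is systematically shifted by the flip, and RT
    # analyses run on correct trials, so the link must hold within-group
    rho_z = 2 * np.sin(np.pi * config.rt_spearman / 6)
    lo_ms, hi_ms = config.slow_rt_range_ms
    for group in (slow & correct & ~is_early, slow & ~(correct & ~is_early)):
        k = int(group.sum())
        if k < 2:
            continue
        z = norm.ppf((rankdata(evidence[group]) - 0.5) / k)
        rt_z = -rho_z * z + np.sqrt(1 - rho_z ** 2) * rng.standard_normal(k)
        rt[group] = lo_ms + (hi_ms - lo_ms) * norm.cdf(rt_z)

    trials = []
    for i in range(n):
        ttype = TrialType.contra if type_sign[i] < 0 else TrialType.ipsi
        if i == 0:
            prev_outcome, prev_choice, prev_stim, prev_el = "none", None, None, None
        else:
            prev_outcome = "rewarded" if prev_rewarded[i] else "unrewarded"
            pt = "contra" if type_sign[i - 1] < 0 else "ipsi"
            prev_choice = pt if correct[i - 1] else ("ipsi" if pt == "contra" else "contra")
            prev_stim = pt
            prev_el = bool(is_early[i - 1])
        trials.append(TrialMeta(
            trial_index=i, trial_type=ttype, correct=bool(correct[i]),
            early_lick=bool(is_early[i]),
            reaction_time_ms=None if is_early[i] else float(rt[i]),
            prev_outcome=prev_outcome, prev_choice=prev_choice,
            prev_stimulus=prev_stim, prev_early_lick=prev_el))

    onsets = np.array([-(dur["pre_sample"] + dur["sample"] + dur["delay"]),
                       -(dur["sample"] + dur["delay"]), -dur["delay"], 0.0])
    edges, labels, centers = _bin_grid(task, config.bin_width_ms)
    binned = BinnedTensor(values=np.transpose(Y, (0, 2, 1)),
                          bin_width_ms=config.bin_width_ms,
                          bin_epoch=labels, bin_centers_s=centers)
    session = SessionData(
        session_id=session_id or f"sim-{session_seed}",
        task=task,
        units=[UnitMeta(unit_id=f"u{u:03d}") for u in range(N)],
        trials=trials,
        epoch_times=np.tile(onsets, (n, 1)),
        spikes=None,
        binned=binned)
    truth = GroundTruth(params=params, latents=X, latent_offsets=offsets,
                        coding_dir=coding_dir, history_dir=history_dir,
                        rt_spearman=config.rt_spearman,
                        history_effect=config.history_effect,
                        error_mechanism=config.error_mechanism,
                        error_flip_times_s=flip_times)
    return session, truth


def generate_benchmark(config: SimConfig, n_sessions: int | None = None):
    """A reproducible multi-session benchmark.

    Returns ``(sessions, truths, manifest)``; the manifest records the
    master seed and each session's seed and size so any session can be
    regenerated independently.
    """
    n_sessions = n_sessions if n_sessions is not None else config.n_sessions
    master = np.random.default_rng(config.seed)
    seeds = master.integers(2 ** 31, size=n_sessions)
    sessions, truths, entries = [], [], []
    for k, s in enumerate(seeds):
        sess, truth = generate_session(config, int(s), session_id=f"sim-{k:02d}")
        sessions.append(sess)
        truths.append(truth)
        entries.append({"session_id": sess.session_id, "seed": int(s),
                        "n_units": sess.n_units, "n_trials": sess.n_trials})
    manifest = {"master_seed": config.seed, "config": asdict(config),
                "sessions": entries}
    return sessions, truths, manifest
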