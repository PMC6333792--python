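"""Event-dependent linear dynamical system: generative model, inference, EM.

The model is a Gaussian latent state-space model whose parameters switch at
externally cued times (behavioral-epoch boundaries).  Within epoch ``s``::

    x(t) = W_mode(s) x(t-1) + w(t-1),   w ~ N(0, diag(q_int(s)))
    r(t) = W_proj(s) x(t)   + r0 + v(t), v ~ N(0, diag(q_ext(s)))
    x(1) ~ N(x0, Q0)

``x`` is the M-dimensional latent ("shared activity space", SAS); ``r`` is the
N-dimensional observed population activity ("full neural space", FNS).  The
epoch of a bin indexes every matrix; a transition into bin ``t`` uses the
parameters of the epoch containing ``t``.

All inference routines operate on an array of trials at once.  Because every
trial shares one bin grid and one parameter set, the covariance recursions are
trial-independent and are computed once; only the means are per-trial.  This
makes EM on hundreds of trials cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

__all__ = [
    "EpochSchedule",
    "EDLDSParams",
    "LatentPosterior",
    "FitTrace",
    "sample_trials",
    "kalman_filter",
    "kalman_smooth",
    "em_fit",
    "infer_sas",
    "EPOCH_NAMES",
]

EPOCH_NAMES = ("pre_sample", "sample", "delay", "response")

_VARIANCE_FLOOR_REL = 1e-6
_JITTER = 1e-8


@dataclass(frozen=True)
class EpochSchedule:
    """Partition of the trial's bin grid into contiguous epochs.

    ``last_bins[s]`` is the index (0-based, inclusive) of the last bin of
    epoch ``s``; epochs tile ``0..T-1``.
    """

    last_bins: tuple[int, ...]
    labels: tuple[str, ...] = EPOCH_NAMES

    def __post_init__(self):
        lb = self.last_bins
        if len(lb) != len(self.labels):
            raise ValueError("one boundary per epoch label required")
        if list(lb) != sorted(set(lb)):
            raise ValueError("epoch boundaries must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return len(self.last_bins)

    @property
    def n_bins(self) -> int:
        return self.last_bins[-1] + 1

    @property
    def epoch_of_bin(self) -> np.ndarray:
        out = np.empty(self.n_bins, dtype=int)
        start = 0
        for s, end in enumerate(self.last_bins):
            out[start : end + 1] = s
            start = end + 1
        return out

    def bins_of(self, s: int) -> np.ndarray:
        start = 0 if s == 0 else self.last_bins[s - 1] + 1
        return np.arange(start, self.last_bins[s] + 1)

    def epoch_n_bins(self) -> np.ndarray:
        return np.diff(np.concatenate([[-1], self.last_bins]))

    @classmethod
    def from_durations(cls, durations_s, bin_width_s, labels=EPOCH_NAMES):
        counts = [max(1, round(d / bin_width_s)) for d in durations_s]
        return cls(tuple(int(b) - 1 for b in np.cumsum(counts)), tuple(labels))

    @classmethod
    def single(cls, n_bins: int, label: str = "all") -> "EpochSchedule":
        return cls((n_bins - 1,), (label,))

    @classmethod
    def from_bin_epochs(cls, bin_epoch, labels=None) -> "EpochSchedule":
        """Build from a per-bin epoch-label sequence (4 contiguous runs)."""
        bin_epoch = list(bin_epoch)
        labs, last = [], []
        for i, lab in enumerate(bin_epoch):
            if not labs or lab != labs[-1]:
                labs.append(lab)
                last.append(i)
            else:
                last[-1] = i
        if len(set(labs)) != len(labs):
            raise ValueError("epoch labels must form contiguous runs")
        return cls(tuple(last), tuple(labs))


@dataclass
class EDLDSParams:
    """Per-epoch parameter set Θ of the model.

    Shapes: ``W_mode (S, M, M)``, ``W_proj (S, N, M)``, ``q_int (S, M)``,
    ``q_ext (S, N)``, ``x0 (M,)``, ``Q0 (M, M)``, ``r0 (N,)``.
    """

    W_mode: np.ndarray
    W_proj: np.ndarray
    q_int: np.ndarray
    q_ext: np.ndarray
    x0: np.ndarray
    Q0: np.ndarray
    r0: np.ndarray

    def __post_init__(self):
        self.W_mode = np.asarray(self.W_mode, dtype=float)
        self.W_proj = np.asarray(self.W_proj, dtype=float)
        self.q_int = np.asarray(self.q_int, dtype=float)
        self.q_ext = np.asarray(self.q_ext, dtype=float)
        self.x0 = np.asarray(self.x0, dtype=float)
        self.Q0 = np.asarray(self.Q0, dtype=float)
        self.r0 = np.asarray(self.r0, dtype=float)
        self.validate()

    @property
    def n_epochs(self) -> int:
        return self.W_mode.shape[0]

    @property
    def M(self) -> int:
        return self.W_mode.shape[1]

    @property
    def N(self) -> int:
        return self.W_proj.shape[1]

    def validate(self):
        S, M = self.W_mode.shape[0], self.W_mode.shape[1]
        N = self.W_proj.shape[1]
        if self.W_mode.shape != (S, M, M) or self.W_proj.shape != (S, N, M):
            raise ValueError("inconsistent W_mode/W_proj shapes")
        if self.q_int.shape != (S, M) or self.q_ext.shape != (S, N):
            raise ValueError("inconsistent noise-variance shapes")
        if self.x0.shape != (M,) or self.Q0.shape != (M, M) or self.r0.shape != (N,):
            raise ValueError("inconsistent initial-state shapes")
        if np.any(self.q_int <= 0) or np.any(self.q_ext <= 0):
            raise ValueError("noise variances must be positive")
        if not np.allclose(self.Q0, self.Q0.T, atol=1e-10):
            raise ValueError("Q0 must be symmetric")
        eig = np.linalg.eigvalsh(0.5 * (self.Q0 + self.Q0.T))
        if eig.min() < -1e-10 * max(1.0, eig.max()):
            raise ValueError("Q0 must be positive semidefinite")

    def drop_neuron(self, i: int) -> "EDLDSParams":
        keep = np.arange(self.N) != i
        return EDLDSParams(
            W_mode=self.W_mode,
            W_proj=self.W_proj[:, keep, :],
            q_int=self.q_int,
            q_ext=self.q_ext[:, keep],
            x0=self.x0,
            Q0=self.Q0,
            r0=self.r0[keep],
        )

    def to_dict(self) -> dict:
        return {
            "W_mode": self.W_mode.tolist(),
            "W_proj": self.W_proj.tolist(),
            "q_int": self.q_int.tolist(),
            "q_ext": self.q_ext.tolist(),
            "x0": self.x0.tolist(),
            "Q0": self.Q0.tolist(),
            "r0": self.r0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EDLDSParams":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


@dataclass
class LatentPosterior:
    """Gaussian posterior over latent trajectories for a batch of trials.

    ``smoothed_means``/``filtered_means``: (n_trials, T, M); covariance
    recursions are data-independent, so ``smoothed_covs`` (T, M, M) and
    ``lag_one_covs`` (T-1, M, M) (``lag_one_covs[t] = Cov(x_{t+1}, x_t)``)
    are shared across trials.
    """

    smoothed_means: np.ndarray
    smoothed_covs: np.ndarray
    lag_one_covs: np.ndarray
    filtered_means: np.ndarray
    filtered_covs: np.ndarray
    loglik: np.ndarray


@dataclass
class FitTrace:
    logliks: list = field(default_factory=list)
    param_deltas: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    seed: int | None = None

    @property
    def final_loglik(self) -> float:
        return self.logliks[-1] if self.logliks else np.nan


# ---------------------------------------------------------------------------
# sampling

def sample_trials(params: EDLDSParams, schedule: EpochSchedule, n_trials: int,
                  seed=None, latent_offsets: np.ndarray | None = None,
                  latent_means: np.ndarray | None = None):
    """Draw trials from the generative model.

    Returns ``(Y, X)`` with ``Y`` (n_trials, T, N) observations and ``X``
    (n_trials, T, M) true latents.  ``latent_offsets`` (n_trials, M) adds a
    constant per-trial offset to the latent path; ``latent_means``
    (n_trials, T, M) adds a deterministic mean path.  Both default to zero
    and exist for building structured synthetic sessions.
    """
    rng = np.random.default_rng(seed)
    T, M, N = schedule.n_bins, params.M, params.N
    epoch = schedule.epoch_of_bin
    X = np.empty((n_trials, T, M))
    # x(1) ~ N(x0, Q0); SVD square root handles singular Q0 exactly
    U, sv, _ = np.linalg.svd(0.5 * (params.Q0 + params.Q0.T))
    L0 = U * np.sqrt(np.maximum(sv, 0.0))
    X[:, 0] = params.x0 + rng.standard_normal((n_trials, M)) @ L0.T
    for t in range(1, T):
        s = epoch[t]
        w = rng.standard_normal((n_trials, M)) * np.sqrt(params.q_int[s])
        X[:, t] = X[:, t - 1] @ params.W_mode[s].T + w
    if latent_offsets is not None:
        X = X + np.asarray(latent_offsets)[:, None, :]
    if latent_means is not None:
        X = X + np.asarray(latent_means)
    Y = np.empty((n_trials, T, N))
    for t in range(T):
        s = epoch[t]
        v = rng.standard_normal((n_trials, N)) * np.sqrt(params.q_ext[s])
        Y[:, t] = X[:, t] @ params.W_proj[s].T + params.r0 + v
    return Y, X


# ---------------------------------------------------------------------------
# inference

def _check_obs(params, schedule, Y):
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[None]
    n, T, N = Y.shape
    if T != schedule.n_bins:
        raise ValueError(f"observations have {T} bins, schedule has {schedule.n_bins}")
    if N != params.N:
        raise ValueError(f"observations have {N} neurons, params expect {params.N}")
    return Y


def _chol_solve(S, B):
    try:
        c, low = linalg.cho_factor(S, lower=True, check_finite=False)
    except linalg.LinAlgError:
        warnings.warn("innovation covariance singular; adding jitter")
        S = S + _JITTER * max(1.0, np.trace(S) / S.shape[0]) * np.eye(S.shape[0])
        c, low = linalg.cho_factor(S, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return linalg.cho_solve((c, low), B, check_finite=False), logdet


def kalman_filter(params: EDLDSParams, schedule: EpochSchedule, Y):
    """Causal Gaussian forward pass with epoch-indexed parameters.

    Returns ``(means, covs, loglik)``: filtered means (n, T, M), filtered
    covariances (T, M, M) shared across trials, and the exact per-trial
    marginal log-likelihood from the prediction-error decomposition.
    """
    Y = _check_obs(params, schedule, Y)
    n, T, N = Y.shape
    M = params.M
    epoch = schedule.epoch_of_bin
    Ybar = Y - params.r0
    means = np.empty((n, T, M))
    covs = np.empty((T, M, M))
    loglik = np.zeros(n)
    I = np.eye(M)
    pred_m = np.broadcast_to(params.x0, (n, M))
    pred_P = params.Q0
    for t in range(T):
        s = epoch[t]
        C = params.W_proj[s]
        R = params.q_ext[s]
        PC = pred_P @ C.T                              # (M, N)
        S = C @ PC + np.diag(R)                        # (N, N)
        innov = Ybar[:, t] - pred_m @ C.T              # (n, N)
        Sinv_innov, logdet = _chol_solve(S, innov.T)   # (N, n)
        K = _chol_solve(S, PC.T)[0].T                  # (M, N)
        means[:, t] = pred_m + Sinv_innov.T @ PC.T     # pred_m + innov @ K.T
        IKC = I - K @ C
        covs[t] = IKC @ pred_P @ IKC.T + (K * R) @ K.T  # Joseph form
        covs[t] = 0.5 * (covs[t] + covs[t].T)
        loglik -= 0.5 * (N * np.log(2 * np.pi) + logdet
                         + np.einsum("tn,nt->t", innov, Sinv_innov))
        if t + 1 < T:
            s1 = epoch[t + 1]
            A = params.W_mode[s1]
            pred_m = means[:, t] @ A.T
            pred_P = A @ covs[t] @ A.T + np.diag(params.q_int[s1])
    return means, covs, loglik


def kalman_smooth(params: EDLDSParams, schedule: EpochSchedule, Y) -> LatentPosterior:
    """RTS smoother over the epoch-indexed forward pass.

    Returns the full :class:`LatentPosterior`, including the lag-one
    cross-covariances needed by the EM M-step.
    """
    Y = _check_obs(params, schedule, Y)
    fm, fP, loglik = kalman_filter(params, schedule, Y)
    n, T, M = fm.shape
    epoch = schedule.epoch_of_bin
    sm = np.empty_like(fm)
    sP = np.empty_like(fP)
    lag = np.empty((max(T - 1, 0), M, M))
    sm[:, T - 1] = fm[:, T - 1]
    sP[T - 1] = fP[T - 1]
    for t in range(T - 2, -1, -1):
        A = params.W_mode[epoch[t + 1]]
        pred_P = A @ fP[t] @ A.T + np.diag(params.q_int[epoch[t + 1]])
        J = np.linalg.solve(pred_P.T, (fP[t] @ A.T).T).T   # fP A' predP^-1
        sm[:, t] = fm[:, t] + (sm[:, t + 1] - fm[:, t] @ A.T) @ J.T
        sP[t] = fP[t] + J @ (sP[t + 1] - pred_P) @ J.T
        sP[t] = 0.5 * (sP[t] + sP[t].T)
        lag[t] = sP[t + 1] @ J.T                           # Cov(x_{t+1}, x_t)
    return LatentPosterior(
        smoothed_means=sm, smoothed_covs=sP, lag_one_covs=lag,
        filtered_means=fm, filtered_covs=fP, loglik=loglik,
    )


def infer_sas(params: EDLDSParams, schedule: EpochSchedule, Y,
              mode: str = "smoothed") -> np.ndarray:
    """Shared-activity-space trajectories E[x_t | data] for a batch of trials.

    ``mode='smoothed'`` conditions on the whole trial; ``mode='forward_only'``
    is the strictly causal estimate (conditions on past and present bins
    only).  Trials are independent: fitting trials and evaluation trials
    (e.g. error trials under correct-trial parameters) are treated alike.
    """
    if mode == "smoothed":
        return kalman_smooth(params, schedule, Y).smoothed_means
    if mode == "forward_only":
        return kalman_filter(params, schedule, Y)[0]
    raise ValueError(f"unknown inference mode {mode!r}")


# ---------------------------------------------------------------------------
# EM

def _init_params(Y, schedule, M, seed, variant):
    from sklearn.decomposition import FactorAnalysis, PCA

    n, T, N = Y.shape
    S = schedule.n_epochs
    r0 = Y.reshape(-1, N).mean(axis=0)
    Xc = Y.reshape(-1, N) - r0
    rng = np.random.default_rng(seed)
    try:
        fa = FactorAnalysis(n_components=M, random_state=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fa.fit(Xc)
        Wp = fa.components_.T                      # (N, M)
        qe = np.maximum(fa.noise_variance_, 1e-4 * Xc.var(axis=0).mean() + 1e-12)
    except Exception:                              # degenerate data
        p = PCA(n_components=M).fit(Xc)
        Wp = (p.components_.T * np.sqrt(np.maximum(p.explained_variance_, 1e-6)))
        qe = np.full(N, max(Xc.var(), 1e-6))
    W_proj = np.repeat(Wp[None], S, axis=0)
    W_mode = np.repeat((0.9 * np.eye(M))[None], S, axis=0)
    q_int = np.full((S, M), 0.19)
    q_ext = np.repeat(qe[None], S, axis=0)
    return EDLDSParams(W_mode=W_mode, W_proj=W_proj, q_int=q_int, q_ext=q_ext,
                       x0=np.zeros(M), Q0=np.eye(M), r0=r0)


def _ridge_inv_solve(B, A):
    """Solve X A = B for X, with ridge jitter if A is ill-conditioned."""
    A = 0.5 * (A + A.T)
    try:
        return np.linalg.solve(A.T, B.T).T
    except np.linalg.LinAlgError:
        warnings.warn("moment matrix singular in M-step; ridge jitter applied")
        A = A + _JITTER * max(1.0, np.trace(A) / A.shape[0]) * np.eye(A.shape[0])
        return np.linalg.solve(A.T, B.T).T


def em_fit(Y, schedule: EpochSchedule, M: int, seed=0, tol: float = 1e-6,
           max_iter: int = 500, variant: str = "edlds",
           init_params: EDLDSParams | None = None):
    """Fit the model by EM with epoch-partitioned M-steps.

    ``Y``: (n_trials, T, N) observations (callers pass correct trials only
    when mirroring the study design).  ``variant`` ties matrices across
    epochs: ``'edlds'`` (none tied), ``'const_wmode'`` (dynamics tied),
    ``'const_wproj'`` (emissions tied), ``'lds'`` (both tied — a plain LDS).

    The E-step is exact per-trial smoothing; the M-step regresses the
    posterior moments epoch by epoch, with the innovation and residual
    covariances projected to their diagonal after each iteration.  ``r0`` is
    held at the per-neuron training mean throughout.  Returns
    ``(EDLDSParams, FitTrace)``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise ValueError("Y must be (n_trials, T, N)")
    n, T, N = Y.shape
    if M >= N:
        raise ValueError("latent dimension must satisfy M < N")
    if variant not in ("edlds", "lds", "const_wmode", "const_wproj"):
        raise ValueError(f"unknown variant {variant!r}")
    S = schedule.n_epochs
    tie_dyn = variant in ("lds", "const_wmode")
    tie_emi = variant in ("lds", "const_wproj")

    params = init_params if init_params is not None else _init_params(Y, schedule, M, seed, variant)
    r0 = params.r0
    Ybar = Y - r0
    yy_diag = np.einsum("ntj,ntj->tj", Ybar, Ybar)      # (T, N)
    var_floor_ext = _VARIANCE_FLOOR_REL * max(Ybar.var(), 1e-12)
    var_floor_int = _VARIANCE_FLOOR_REL

    trace = FitTrace(seed=seed)
    prev_ll = -np.inf
    degenerate = Ybar.var() < 1e-12
    for it in range(max_iter):
        post = kalman_smooth(params, schedule, Y)
        ll = float(post.loglik.sum())
        trace.logliks.append(ll)
        trace.n_iter = it + 1

        sm, sP, lag = post.smoothed_means, post.smoothed_covs, post.lag_one_covs
        Exx = np.einsum("nti,ntj->tij", sm, sm) + n * sP          # (T, M, M)
        Exy = np.einsum("nti,ntj->tij", sm, Ybar)                 # (T, M, N)
        Ex1x0 = np.einsum("nti,ntj->tij",
                          sm[:, 1:], sm[:, :-1]) + n * lag        # (T-1, M, M)

        new = _m_step(params, schedule, Exx, Exy, Ex1x0, yy_diag, n,
                      tie_dyn, tie_emi, var_floor_ext, var_floor_int)
        # initial-state update pooled over trials
        x0 = sm[:, 0].mean(axis=0)
        d0 = sm[:, 0] - x0
        Q0 = sP[0] + d0.T @ d0 / n
        Q0 = 0.5 * (Q0 + Q0.T) + var_floor_int * np.eye(M)
        delta = _param_delta(params, new)
        params = replace(new, x0=x0, Q0=Q0, r0=r0)
        trace.param_deltas.append(delta)

        if it > 0:
            rel = (ll - prev_ll) / (abs(prev_ll) + 1e-12)
            if ll < prev_ll - 1e-6 * abs(prev_ll) and not degenerate:
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{prev_ll:.6g} -> {ll:.6g}")
            if abs(rel) < tol:
                trace.converged = True
                break
        prev_ll = ll
    if degenerate and not trace.converged:
        warnings.warn("degenerate (near-constant) data; EM flagged non-converged")
    return params, trace


def _m_step(params, schedule, Exx, Exy, Ex1x0, yy_diag, n,
            tie_dyn, tie_emi, floor_ext, floor_int):
    S, M, N = params.n_epochs, params.M, params.N
    W_proj = np.empty_like(params.W_proj)
    W_mode = np.empty_like(params.W_mode)
    q_ext = np.empty_like(params.q_ext)
    q_int = np.empty_like(params.q_int)

    emi_groups = [list(range(S))] if tie_emi else [[s] for s in range(S)]
    for group in emi_groups:
        bins = np.concatenate([schedule.bins_of(s) for s in group])
        Sxx = Exx[bins].sum(axis=0)
        Sxy = Exy[bins].sum(axis=0)                    # (M, N)
        Wp = _ridge_inv_solve(Sxy.T, Sxx)              # (N, M)
        resid = yy_diag[bins].sum(axis=0) - np.einsum("nm,mn->n", Wp, Sxy)
        qe = np.maximum(resid / (n * len(bins)), floor_ext)
        for s in group:
            W_proj[s] = Wp
            q_ext[s] = qe

    dyn_groups = [list(range(S))] if tie_dyn else [[s] for s in range(S)]
    for group in dyn_groups:
        # transitions into bins of epoch s (bin 0 has no incoming transition)
        tr = np.concatenate([schedule.bins_of(s) for s in group])
        tr = tr[tr >= 1]
        Sx1x0 = Ex1x0[tr - 1].sum(axis=0)              # Cov terms of (x_t, x_{t-1})
        Sx0x0 = Exx[tr - 1].sum(axis=0)
        Sx1x1 = Exx[tr].sum(axis=0)
        Wm = _ridge_inv_solve(Sx1x0, Sx0x0)            # (M, M)
        resid = Sx1x1 - Wm @ Sx1x0.T
        resid = 0.5 * (resid + resid.T)
        qi = np.maximum(np.diag(resid) / (n * len(tr)), floor_int)
        for s in group:
            W_mode[s] = Wm
            q_int[s] = qi

    return EDLDSParams(W_mode=W_mode, W_proj=W_proj, q_int=q_int, q_ext=q_ext,
                       x0=params.x0, Q0=params.Q0, r0=params.r0)


def _param_delta(a: EDLDSParams, b: EDLDSParams) -> float:
    return float(sum(np.linalg.norm(getattr(a, f) - getattr(b, f))
                     for f in ("W_mode", "W_proj", "q_int", "q_ext")))
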