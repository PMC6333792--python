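"""Independent oracles for testing the state-space machinery.

Everything here is deliberately written from first principles (dense joint
Gaussians, per-trial textbook recursions) and shares no code with the
package's vectorized implementation.
"""

import numpy as np


def joint_gaussian_posterior(params, schedule, y):
    """Exact posterior over the latent stack by conditioning the dense joint
    Gaussian of (x_1..x_T, r_1..r_T) on the observations of ONE trial.

    Returns dict with smoothed means (T, M), marginal covariances (T, M, M),
    lag-one cross-covariances Cov(x_{t+1}, x_t) (T-1, M, M), filtered means
    (T, M) (conditioning on prefixes), and the marginal log-density.
    """
    T = schedule.n_bins
    M, N = params.M, params.N
    ep = schedule.epoch_of_bin
    mx = np.zeros((T, M))
    mx[0] = params.x0
    Cx = np.zeros((T * M, T * M))
    Cx[:M, :M] = params.Q0
    for t in range(1, T):
        A = params.W_mode[ep[t]]
        mx[t] = A @ mx[t - 1]
        for u in range(t):
            blk = A @ Cx[(t - 1) * M:t * M, u * M:(u + 1) * M]
            Cx[t * M:(t + 1) * M, u * M:(u + 1) * M] = blk
            Cx[u * M:(u + 1) * M, t * M:(t + 1) * M] = blk.T
        Cx[t * M:(t + 1) * M, t * M:(t + 1) * M] = (
            A @ Cx[(t - 1) * M:t * M, (t - 1) * M:t * M] @ A.T
            + np.diag(params.q_int[ep[t]]))
    H = np.zeros((T * N, T * M))
    for t in range(T):
        H[t * N:(t + 1) * N, t * M:(t + 1) * M] = params.W_proj[ep[t]]
    mr = H @ mx.ravel() + np.tile(params.r0, T)
    Srr = H @ Cx @ H.T + np.diag(
        np.concatenate([params.q_ext[ep[t]] for t in range(T)]))
    Sxr = Cx @ H.T
    resid = y.ravel() - mr
    sol = np.linalg.solve(Srr, resid)
    mean = (mx.ravel() + Sxr @ sol).reshape(T, M)
    cov = Cx - Sxr @ np.linalg.solve(Srr, Sxr.T)
    covs = np.stack([cov[t * M:(t + 1) * M, t * M:(t + 1) * M] for t in range(T)])
    lag = np.stack([cov[(t + 1) * M:(t + 2) * M, t * M:(t + 1) * M]
                    for t in range(T - 1)]) if T > 1 else np.zeros((0, M, M))
    sign, logdet = np.linalg.slogdet(Srr)
    loglik = -0.5 * (T * N * np.log(2 * np.pi) + logdet + resid @ sol)
    filtered = np.empty((T, M))
    for t in range(T):
        k = (t + 1) * N
        sol_t = np.linalg.solve(Srr[:k, :k], y.ravel()[:k] - mr[:k])
        filtered[t] = (mx.ravel() + Sxr[:, :k] @ sol_t).reshape(T, M)[t]
    return {"mean": mean, "covs": covs, "lag": lag, "loglik": loglik,
            "filtered": filtered}


def plain_lds_em(Y, M, init, n_iter):
    """Textbook EM for a single-regime linear-Gaussian state-space model with
    diagonal noise covariances and a fixed observation offset.

    ``Y``: (n, T, N); ``init``: dict with A (M,M), C (N,M), q (M,), r (N,),
    x0 (M,), Q0 (M,M), d (N,) — the offset d stays fixed (training mean).
    Per-trial loops throughout; returns the updated dict and the per-
    iteration log-likelihoods.
    """
    Y = np.asarray(Y, dtype=float)
    n, T, N = Y.shape
    A = np.array(init["A"], dtype=float)
    C = np.array(init["C"], dtype=float)
    q = np.array(init["q"], dtype=float)
    r = np.array(init["r"], dtype=float)
    x0 = np.array(init["x0"], dtype=float)
    Q0 = np.array(init["Q0"], dtype=float)
    d = np.array(init["d"], dtype=float)
    logliks = []
    for _ in range(n_iter):
        S_xx = np.zeros((M, M))          # sum E[x_t x_t'] over all t, trials
        S_xx_head = np.zeros((M, M))     # over t = 0..T-2
        S_xx_tail = np.zeros((M, M))     # over t = 1..T-1
        S_lag = np.zeros((M, M))         # sum E[x_t x_{t-1}']
        S_xy = np.zeros((M, N))
        S_yy = np.zeros(N)
        S_x1 = np.zeros(M)
        S_x1x1 = np.zeros((M, M))
        ll = 0.0
        for i in range(n):
            y = Y[i] - d
            # forward pass
            fm = np.zeros((T, M)); fP = np.zeros((T, M, M))
            pm, pP = x0.copy(), Q0.copy()
            for t in range(T):
                S = C @ pP @ C.T + np.diag(r)
                Sinv = np.linalg.inv(S)
                innov = y[t] - C @ pm
                K = pP @ C.T @ Sinv
                fm[t] = pm + K @ innov
                fP[t] = pP - K @ C @ pP
                ll += -0.5 * (N * np.log(2 * np.pi)
                              + np.linalg.slogdet(S)[1] + innov @ Sinv @ innov)
                pm, pP = A @ fm[t], A @ fP[t] @ A.T + np.diag(q)
            # backward pass
            sm = np.zeros((T, M)); sP = np.zeros((T, M, M))
            sm[-1], sP[-1] = fm[-1], fP[-1]
            lag1 = np.zeros((T - 1, M, M))
            for t in range(T - 2, -1, -1):
                pP = A @ fP[t] @ A.T + np.diag(q)
                J = fP[t] @ A.T @ np.linalg.inv(pP)
                sm[t] = fm[t] + J @ (sm[t + 1] - A @ fm[t])
                sP[t] = fP[t] + J @ (sP[t + 1] - pP) @ J.T
                lag1[t] = sP[t + 1] @ J.T
            for t in range(T):
                Exx = sP[t] + np.outer(sm[t], sm[t])
                S_xx += Exx
                S_xy += np.outer(sm[t], y[t])
                S_yy += y[t] ** 2
                if t < T - 1:
                    S_xx_head += Exx
                if t > 0:
                    S_xx_tail += Exx
                    S_lag += lag1[t - 1] + np.outer(sm[t], sm[t - 1])
            S_x1 += sm[0]
            S_x1x1 += sP[0] + np.outer(sm[0], sm[0])
        logliks.append(ll)
        # M-step (diagonal noises, fixed d)
        C = (S_xy.T) @ np.linalg.inv(S_xx)
        r = (S_yy - np.einsum("nm,mn->n", C, S_xy)) / (n * T)
        A = S_lag @ np.linalg.inv(S_xx_head)
        q = np.diag(S_xx_tail - A @ S_lag.T) / (n * (T - 1))
        x0 = S_x1 / n
        Q0 = S_x1x1 / n - np.outer(x0, x0)
        Q0 = 0.5 * (Q0 + Q0.T)
    return {"A": A, "C": C, "q": q, "r": r, "x0": x0, "Q0": Q0, "d": d}, logliks


def random_instance(rng, T_max=8, N_max=3, M_max=2, n_epochs_max=3):
    """A random small model instance for oracle-equivalence testing."""
    from edlds.model import EDLDSParams, EpochSchedule

    T = int(rng.integers(2, T_max + 1))
    M = int(rng.integers(1, M_max + 1))
    N = int(rng.integers(1, N_max + 1))
    S = int(rng.integers(1, min(n_epochs_max, T) + 1))
    bounds = np.sort(rng.choice(np.arange(T - 1), size=S - 1, replace=False)) \
        if S > 1 else np.array([], dtype=int)
    last_bins = tuple(list(bounds) + [T - 1])
    sched = EpochSchedule(last_bins, tuple(f"e{k}" for k in range(S)))
    L = rng.normal(0, 1, (M, M))
    params = EDLDSParams(
        W_mode=rng.normal(0, 0.6, (S, M, M)),
        W_proj=rng.normal(0, 1.0, (S, N, M)),
        q_int=rng.uniform(0.2, 1.5, (S, M)),
        q_ext=rng.uniform(0.2, 1.5, (S, N)),
        x0=rng.normal(0, 1, M),
        Q0=L @ L.T + 0.3 * np.eye(M),
        r0=rng.normal(0, 1, N))
    return params, sched
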