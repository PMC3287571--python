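"""Simulation and EM estimation of the linear-Gaussian state space model.

EM alternates the exact E-step (Kalman filter + RTS smoother, see
:mod:`ssmgrn.kalman`) with closed-form M-step updates of F, H, Q, the
diagonal of R, and mu0 from the smoothed sufficient statistics. Sigma0 is
held fixed at the identity. Each iteration cannot decrease the marginal
log-likelihood.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionDataset, SSMParameters
from .kalman import FilterSmootherResult, kalman_filter_smoother

__all__ = ["EMConfig", "EMTrace", "FittingError", "simulate_ssm", "em_fit", "pca_init"]

_R_FLOOR = 1e-10  # keeps the diagonal of R strictly positive


class FittingError(RuntimeError):
    pass


@dataclass(frozen=True)
class EMConfig:
    """EM settings.

    ``tol`` is the relative log-likelihood change |dll| / (1 + |ll|) below
    which iteration stops. ``n_restarts`` counts initializations: the first
    is the deterministic PCA initialization, further ones are seeded random
    perturbations of it; the restart with the best final log-likelihood wins,
    ties going to the lowest restart index.
    """

    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class EMTrace:
    """Convergence record of the winning restart.

    ``logliks[0]`` is the initialization's marginal log-likelihood and
    ``logliks[i]`` the value after the i-th M-step, so ``iterations ==
    len(logliks) - 1`` counts M-step updates and the returned parameters
    attain exactly ``logliks[-1]``.
    """

    logliks: tuple
    iterations: int
    converged: bool
    config_echo: EMConfig
    restart_index: int = 0


def simulate_ssm(params: SSMParameters, T: int, seed: int):
    """Draw one trajectory of length ``T`` from the model.

    Returns ``(X, dataset)`` where ``X`` is the (m, T) hidden trajectory and
    ``dataset`` the observed (l, T) :class:`ExpressionDataset`. The same seed
    gives identical output.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    m, l = params.m, params.l
    X = np.empty((m, T))
    Y = np.empty((l, T))
    x = rng.multivariate_normal(params.mu0, params.Sigma0, method="svd")
    for t in range(T):
        if t > 0:
            x = params.F @ x + rng.multivariate_normal(np.zeros(m), params.Q, method="svd")
        X[:, t] = x
        Y[:, t] = params.H @ x + rng.multivariate_normal(np.zeros(l), params.R, method="svd")
    return X, ExpressionDataset(Y)


def pca_init(data: ExpressionDataset, m: int) -> SSMParameters:
    """Deterministic data-driven initialization.

    H is set to the first ``m`` principal-component loadings of the (centered)
    data, initial states to the PC scores, F by least-squares regression of
    scores at t on t-1, Q and the diagonal of R to sample residual variances,
    mu0 to the first score column, and Sigma0 to the identity.
    """
    Yc = data.centered().values
    l, T = Yc.shape
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    H = U[:, :m].copy()
    Z = (s[:m, None] * Vt[:m])  # m x T scores
    if T >= 2:
        Z0, Z1 = Z[:, :-1], Z[:, 1:]
        G = Z0 @ Z0.T
        F = np.linalg.lstsq(G + 1e-8 * np.eye(m), (Z1 @ Z0.T).T, rcond=None)[0].T
        resid = Z1 - F @ Z0
        Q = resid @ resid.T / max(T - 1, 1) + 1e-4 * np.eye(m)
    else:
        F = np.zeros((m, m))
        Q = np.eye(m)
    E = Yc - H @ Z
    r = E.var(axis=1)
    R = np.diag(np.maximum(r, 1e-4))
    return SSMParameters(F=F, H=H, Q=0.5 * (Q + Q.T), R=R, mu0=Z[:, 0],
                         Sigma0=np.eye(m))


def _perturb(params: SSMParameters, rng: np.random.Generator) -> SSMParameters:
    scale = 0.1
    F = params.F + scale * max(np.abs(params.F).max(), 0.1) * rng.standard_normal(params.F.shape)
    H = params.H + scale * max(np.abs(params.H).max(), 0.1) * rng.standard_normal(params.H.shape)
    return SSMParameters(F=F, H=H, Q=params.Q, R=params.R,
                         mu0=params.mu0, Sigma0=params.Sigma0)


def m_step(Yc: np.ndarray, params: SSMParameters,
           sm: FilterSmootherResult) -> SSMParameters:
    """Closed-form M-step from smoothed sufficient statistics.

    Updates F, H, full symmetric Q, diagonal R and mu0; Sigma0 is not
    re-estimated. ``Yc`` must be the centered (l, T) data matrix used in the
    E-step.
    """
    s = sm.smoothed_means
    P = sm.smoothed_covs
    L = sm.lag_one_covs
    m, T = s.shape
    # second moments E[x_t x_t'] and E[x_t x_{t-1}']
    M = P + np.einsum("it,jt->ijt", s, s)  # m x m x T
    Sxx_all = M.sum(axis=2)
    Sxx0 = Sxx_all - M[:, :, T - 1]
    Sxx1 = Sxx_all - M[:, :, 0]
    Sx1x0 = L.sum(axis=2) + s[:, 1:] @ s[:, :-1].T
    Syx = Yc @ s.T  # l x m

    F = np.linalg.solve(Sxx0.T, Sx1x0.T).T
    Q = (Sxx1 - F @ Sx1x0.T) / (T - 1)
    Q = 0.5 * (Q + Q.T)
    # guard against tiny negative eigenvalues from roundoff
    Q += _R_FLOOR * np.eye(m)
    H = np.linalg.solve(Sxx_all.T, Syx.T).T
    Syy_diag = np.einsum("it,it->i", Yc, Yc)
    r = (Syy_diag - np.einsum("ij,ij->i", H, Syx)) / T
    R = np.diag(np.maximum(r, _R_FLOOR))
    return SSMParameters(F=F, H=H, Q=Q, R=R, mu0=s[:, 0], Sigma0=params.Sigma0)


def _run_em(dataset_c: ExpressionDataset, params: SSMParameters,
            config: EMConfig):
    Yc = dataset_c.values
    sm = kalman_filter_smoother(params, dataset_c)
    logliks = [sm.loglik]
    converged = False
    for it in range(1, config.max_iter + 1):
        params = m_step(Yc, params, sm)
        sm = kalman_filter_smoother(params, dataset_c)
        ll = sm.loglik
        if not np.isfinite(ll):
            raise FittingError(f"non-finite log-likelihood at EM iteration {it}")
        logliks.append(ll)
        if abs(ll - logliks[-2]) / (1.0 + abs(ll)) < config.tol:
            converged = True
            break
    return params, logliks, converged


def em_fit(data: ExpressionDataset, m: int, config: EMConfig | None = None,
           init: SSMParameters | None = None):
    """Maximum-likelihood fit of an m-dimensional model by EM.

    Gene rows are mean-centered internally before fitting (the model has no
    intercept). Returns ``(SSMParameters, EMTrace)`` for the best restart.

    Raises
    ------
    ValueError
        If ``m`` is outside [1, min(l, T)].
    FittingError
        If the log-likelihood diverges or becomes non-finite.
    """
    config = config or EMConfig()
    l, T = data.n_genes, data.n_times
    if T < 2:
        raise ValueError("need at least 2 time points to fit")
    if not 1 <= m <= min(l, T):
        raise ValueError(f"m must be in [1, min(l, T)] = [1, {min(l, T)}], got {m}")
    if np.any(data.values.std(axis=1) == 0.0):
        warnings.warn("constant gene rows present; they are centered to zero "
                      "and cannot earn edges", stacklevel=2)
    dataset_c = data.centered()
    base = init if init is not None else pca_init(data, m)

    best = None
    for r in range(config.n_restarts):
        if r == 0:
            start = base
        else:
            rng = np.random.default_rng(np.uint32(config.seed) + np.uint32(r))
            start = _perturb(base, rng)
        params, logliks, converged = _run_em(dataset_c, start, config)
        if best is None or logliks[-1] > best[1][-1]:  # ties keep lowest index
            best = (params, logliks, converged, r)
    params, logliks, converged, r = best
    trace = EMTrace(logliks=tuple(logliks), iterations=len(logliks) - 1,
                    converged=converged, config_echo=config, restart_index=r)
    return params, trace
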