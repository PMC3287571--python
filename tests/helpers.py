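"""Independent oracles used by the tests.

Everything here is written as straight-line / brute-force code on purpose:
it must stay independent of the package's own recursions so that agreement
is evidence, not tautology.
"""
from __future__ import annotations

import numpy as np
import scipy.stats

from ssmgrn import ExpressionDataset, SSMParameters


def stacked_joint_gaussian(params: SSMParameters, T: int):
    """Exact joint distribution of (x_1..x_T, y_1..y_T) built directly from
    the model matrices via the linear map from the independent noise terms.

    Returns (mean_x, mean_y, cov_xx, cov_yy, cov_xy) with x and y stacked
    time-major (block t is x_{t+1} resp. y_{t+1}).
    """
    m, l = params.m, params.l
    n = m * T
    mean_x = np.zeros(n)
    mean_x[:m] = params.mu0
    for t in range(1, T):
        mean_x[t * m:(t + 1) * m] = params.F @ mean_x[(t - 1) * m:t * m]
    # x deviations are a linear map A of u = [x1 - mu0, w_2, ..., w_T]
    A = np.zeros((n, n))
    cov_u = np.zeros((n, n))
    cov_u[:m, :m] = params.Sigma0
    for t in range(1, T):
        cov_u[t * m:(t + 1) * m, t * m:(t + 1) * m] = params.Q
    for t in range(T):
        for s in range(t + 1):
            A[t * m:(t + 1) * m, s * m:(s + 1) * m] = \
                np.linalg.matrix_power(params.F, t - s)
    cov_xx = A @ cov_u @ A.T
    Hbig = np.kron(np.eye(T), params.H)
    mean_y = Hbig @ mean_x
    cov_yy = Hbig @ cov_xx @ Hbig.T + np.kron(np.eye(T), params.R)
    cov_xy = cov_xx @ Hbig.T
    return mean_x, mean_y, cov_xx, cov_yy, cov_xy


def joint_loglik(params: SSMParameters, data: ExpressionDataset) -> float:
    """Marginal log p(y_1..T) from the stacked joint Gaussian."""
    T = data.n_times
    _, mean_y, _, cov_yy, _ = stacked_joint_gaussian(params, T)
    y = data.values.T.ravel()
    return float(scipy.stats.multivariate_normal(mean_y, cov_yy,
                                                 allow_singular=True).logpdf(y))


def joint_smoothed_moments(params: SSMParameters, data: ExpressionDataset):
    """Conditional mean/cov of the stacked hidden states given all data."""
    T = data.n_times
    mean_x, mean_y, cov_xx, cov_yy, cov_xy = stacked_joint_gaussian(params, T)
    y = data.values.T.ravel()
    solve = np.linalg.solve(cov_yy, np.column_stack([y - mean_y, cov_xy.T]))
    cond_mean = mean_x + cov_xy @ solve[:, 0]
    cond_cov = cov_xx - cov_xy @ solve[:, 1:]
    return cond_mean, cond_cov


def mstep_reference(Yc: np.ndarray, smoothed_means: np.ndarray,
                    smoothed_covs: np.ndarray, lag_one_covs: np.ndarray,
                    Sigma0: np.ndarray):
    """Closed-form M-step written as explicit sums and loops."""
    m, T = smoothed_means.shape
    l = Yc.shape[0]
    s = smoothed_means
    M = [smoothed_covs[:, :, t] + np.outer(s[:, t], s[:, t]) for t in range(T)]
    C = [lag_one_covs[:, :, t - 1] + np.outer(s[:, t], s[:, t - 1])
         for t in range(1, T)]
    A = np.zeros((m, m))
    B = np.zeros((m, m))
    for t in range(1, T):
        A += C[t - 1]
        B += M[t - 1]
    F = A @ np.linalg.inv(B)
    Q = np.zeros((m, m))
    for t in range(1, T):
        Q += M[t] - F @ C[t - 1].T - C[t - 1] @ F.T + F @ M[t - 1] @ F.T
    Q /= T - 1
    Q = 0.5 * (Q + Q.T)
    Syx = np.zeros((l, m))
    Sall = np.zeros((m, m))
    for t in range(T):
        Syx += np.outer(Yc[:, t], s[:, t])
        Sall += M[t]
    H = Syx @ np.linalg.inv(Sall)
    r = np.zeros(l)
    for t in range(T):
        resid_sq = Yc[:, t] ** 2 - 2 * Yc[:, t] * (H @ s[:, t])
        r += resid_sq
        r += np.diag(H @ M[t] @ H.T)
    r /= T
    return F, H, Q, np.diag(r), s[:, 0].copy(), Sigma0.copy()


def random_small_params(rng: np.random.Generator, m: int, l: int) -> SSMParameters:
    """A well-conditioned random model for exactness checks."""
    F = 0.6 * rng.standard_normal((m, m)) / np.sqrt(m)
    H = rng.standard_normal((l, m))
    q = rng.standard_normal((m, m + 1))
    Q = q @ q.T / (m + 1) + 0.1 * np.eye(m)
    R = np.diag(rng.uniform(0.2, 1.0, l))
    mu0 = rng.standard_normal(m)
    s0 = rng.standard_normal((m, m + 1))
    Sigma0 = s0 @ s0.T / (m + 1) + 0.1 * np.eye(m)
    return SSMParameters(F=F, H=H, Q=Q, R=R, mu0=mu0, Sigma0=Sigma0)


def random_orthogonal(rng: np.random.Generator, m: int) -> np.ndarray:
    A = rng.standard_normal((m, m))
    Qm, Rm = np.linalg.qr(A)
    return Qm * np.sign(np.diag(Rm))


def spectrum_dataset(eigenvalues, T: int) -> ExpressionDataset:
    """A dataset whose gene-covariance eigenvalues equal ``eigenvalues``.

    Rows are built from orthonormal time patterns orthogonal to the constant
    vector, so row-centering leaves them unchanged.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    k = len(lam)
    assert T >= k + 1
    rng = np.random.default_rng(12345)
    basis = np.column_stack([np.ones(T)] + [rng.standard_normal(T) for _ in range(k)])
    Qb, _ = np.linalg.qr(basis)
    V = Qb[:, 1:1 + k]  # orthonormal, orthogonal to ones
    Y = np.diag(np.sqrt(lam * (T - 1))) @ V.T  # k genes x T
    return ExpressionDataset(Y)
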