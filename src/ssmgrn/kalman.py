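"""Exact inference for the linear-Gaussian state space model.

Forward Kalman filter, Rauch-Tung-Striebel (RTS) backward smoother, lag-one
smoothed covariances, and the prediction-error-decomposition marginal
log-likelihood. These are the exact E-step quantities required by EM.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datatypes import ExpressionDataset, SSMParameters

__all__ = ["FilterSmootherResult", "kalman_filter_smoother", "NumericalError"]

# jitter-retry policy for near-singular covariance solves: start tiny,
# escalate x10 at most three times before declaring failure
_JITTER0 = 1e-10
_JITTER_ESCALATIONS = 3


class NumericalError(RuntimeError):
    """Raised when a covariance solve fails even after jitter escalation."""


@dataclass(frozen=True)
class FilterSmootherResult:
    """Filtered, predicted and smoothed moments plus the marginal log-likelihood.

    Time is the trailing axis: ``smoothed_means[:, t]`` is E[x_{t+1} | y_1..T]
    (0-based t). ``lag_one_covs[:, :, t]`` is Cov(x_{t+2}, x_{t+1} | y_1..T).
    ``loglik`` is log p(y_1..T | theta) in nats.
    """

    filtered_means: np.ndarray
    filtered_covs: np.ndarray
    predicted_means: np.ndarray
    predicted_covs: np.ndarray
    smoothed_means: np.ndarray
    smoothed_covs: np.ndarray
    lag_one_covs: np.ndarray
    loglik: float


def _solve_psd(A: np.ndarray, B: np.ndarray):
    """Solve A X = B for symmetric PSD A with jitter retries.

    Returns ``(X, logdet)`` where logdet is log|A + jitter I| from the
    successful Cholesky factorization.
    """
    A = 0.5 * (A + A.T)
    jitter = 0.0
    for attempt in range(_JITTER_ESCALATIONS + 2):
        try:
            c, low = scipy.linalg.cho_factor(A + jitter * np.eye(A.shape[0]),
                                             check_finite=False)
            X = scipy.linalg.cho_solve((c, low), B, check_finite=False)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            return X, logdet
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
            if attempt > _JITTER_ESCALATIONS:
                break
            jitter = _JITTER0 if jitter == 0.0 else jitter * 10.0
    raise NumericalError("singular covariance: Cholesky failed after jitter escalation")


def _sym(A: np.ndarray) -> np.ndarray:
    return 0.5 * (A + A.T)


def kalman_filter_smoother(params: SSMParameters,
                           data: ExpressionDataset) -> FilterSmootherResult:
    """Run the exact filter/smoother on ``data`` under ``params``.

    Parameters
    ----------
    params : SSMParameters
    data : ExpressionDataset
        Must have ``data.n_genes == params.l``. The data are used as given
        (callers that assume a zero-mean model center beforehand).

    Returns
    -------
    FilterSmootherResult

    Raises
    ------
    NumericalError
        If an innovation covariance stays singular through the jitter-retry
        policy.
    """
    if data.n_genes != params.l:
        raise ValueError(f"data has {data.n_genes} genes but model expects {params.l}")
    Y = data.values
    m, l, T = params.m, params.l, data.n_times
    F, H, Q, R = params.F, params.H, params.Q, params.R

    pred_means = np.empty((m, T))
    pred_covs = np.empty((m, m, T))
    filt_means = np.empty((m, T))
    filt_covs = np.empty((m, m, T))
    loglik = 0.0
    log2pi = np.log(2.0 * np.pi)

    x_pred = params.mu0.copy()
    P_pred = params.Sigma0.copy()
    for t in range(T):
        pred_means[:, t] = x_pred
        pred_covs[:, :, t] = P_pred
        # innovation
        innov = Y[:, t] - H @ x_pred
        S = _sym(H @ P_pred @ H.T + R)
        PHt = P_pred @ H.T
        solved, logdetS = _solve_psd(S, np.column_stack([innov, PHt.T]))
        Sinv_innov = solved[:, 0]
        K = solved[:, 1:].T  # P H' S^{-1}
        loglik += -0.5 * (l * log2pi + logdetS + innov @ Sinv_innov)
        x_filt = x_pred + K @ innov
        P_filt = _sym(P_pred - K @ H @ P_pred)
        filt_means[:, t] = x_filt
        filt_covs[:, :, t] = P_filt
        if t < T - 1:
            x_pred = F @ x_filt
            P_pred = _sym(F @ P_filt @ F.T + Q)

    # RTS backward pass
    sm_means = np.empty((m, T))
    sm_covs = np.empty((m, m, T))
    lag_one = np.empty((m, m, max(T - 1, 0)))
    sm_means[:, T - 1] = filt_means[:, T - 1]
    sm_covs[:, :, T - 1] = filt_covs[:, :, T - 1]
    for t in range(T - 2, -1, -1):
        P_next_pred = pred_covs[:, :, t + 1]
        # J_t = P_filt F' P_pred(t+1)^{-1}
        try:
            Jt_T, _ = _solve_psd(P_next_pred, F @ filt_covs[:, :, t])
            J = Jt_T.T
        except NumericalError:
            J = filt_covs[:, :, t] @ F.T @ np.linalg.pinv(P_next_pred)
        sm_means[:, t] = filt_means[:, t] + J @ (sm_means[:, t + 1] - pred_means[:, t + 1])
        sm_covs[:, :, t] = _sym(
            filt_covs[:, :, t] + J @ (sm_covs[:, :, t + 1] - P_next_pred) @ J.T
        )
        # Cov(x_{t+1}, x_t | Y) = P^s_{t+1} J_t'
        lag_one[:, :, t] = sm_covs[:, :, t + 1] @ J.T

    if not np.isfinite(loglik):
        raise NumericalError("non-finite marginal log-likelihood")
    return FilterSmootherResult(
        filtered_means=filt_means,
        filtered_covs=filt_covs,
        predicted_means=pred_means,
        predicted_covs=pred_covs,
        smoothed_means=sm_means,
        smoothed_covs=sm_covs,
        lag_one_covs=lag_one,
        loglik=float(loglik),
    )
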