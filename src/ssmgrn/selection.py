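"""Choosing the hidden dimension m: BIC, the PCA residual-eigenvalue rule,
or a fixed user value.

BIC here is the penalized log-likelihood  ll - (1/2) * N_theta * ln N,
maximized over candidate dimensions. N_theta counts the free scalars the
M-step actually updates (F, H, symmetric Q, diagonal R, mu0; Sigma0 is held
fixed). N defaults to the number of scalar observations l*T; counting time
points instead (N = T) is available via ``n_obs="time"``.

The PCA rule picks the smallest m whose discarded eigenvalue mass
sum_{k>m} lambda_k / sum_k lambda_k falls at or below a cutoff fraction
(0.2 by default).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionDataset
from .ssm import EMConfig, em_fit

__all__ = [
    "SelectionReport",
    "compute_bic",
    "count_parameters",
    "select_m_bic",
    "pca_eigenvalues",
    "select_m_pca",
]

_EIG_ZERO_REL = 1e-12  # eigenvalues below this fraction of the largest are zero


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of a hidden-dimension selection.

    ``criterion_values[i]`` is the BIC value (method "bic") or residual
    eigenvalue fraction after keeping ``candidate_ms[i]`` components
    (method "pca"). Failed BIC candidates carry NaN.
    """

    candidate_ms: tuple
    criterion_values: tuple
    chosen_m: int
    method: str

    def __post_init__(self) -> None:
        if len(self.candidate_ms) != len(self.criterion_values):
            raise ValueError("candidate_ms and criterion_values length mismatch")
        if self.chosen_m not in self.candidate_ms:
            raise ValueError("chosen_m not among candidates")


def compute_bic(loglik: float, n_params: int, n_data: int) -> float:
    """Penalized log-likelihood: ``loglik - 0.5 * n_params * ln(n_data)``."""
    if n_data < 1:
        raise ValueError("n_data must be >= 1")
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    return float(loglik) - 0.5 * n_params * np.log(n_data)


def count_parameters(m: int, l: int) -> int:
    """Free scalars estimated by EM: F (m^2) + H (l*m) + symmetric Q
    (m(m+1)/2) + diagonal R (l) + mu0 (m)."""
    if m < 1 or l < 1:
        raise ValueError("m and l must be >= 1")
    return m * m + l * m + m * (m + 1) // 2 + l + m


def select_m_bic(data: ExpressionDataset, candidates, config: EMConfig | None = None,
                 n_obs: str = "scalar") -> SelectionReport:
    """Fit each candidate m by EM and keep the one with the largest BIC.

    Ties break toward smaller m. Candidates whose fit fails are recorded with
    NaN and excluded; if every candidate fails an error is raised.
    """
    candidates = tuple(int(c) for c in candidates)
    if not candidates:
        raise ValueError("no candidate dimensions")
    l, T = data.n_genes, data.n_times
    if n_obs == "scalar":
        n_data = l * T
    elif n_obs == "time":
        n_data = T
    else:
        raise ValueError("n_obs must be 'scalar' or 'time'")
    values = []
    for m in candidates:
        try:
            _, trace = em_fit(data, m, config)
            values.append(compute_bic(trace.logliks[-1], count_parameters(m, l), n_data))
        except Exception:
            values.append(np.nan)
    if np.all(np.isnan(values)):
        raise RuntimeError("all candidate fits failed")
    order = sorted(range(len(candidates)),
                   key=lambda i: (-(values[i] if np.isfinite(values[i]) else -np.inf),
                                  candidates[i]))
    chosen = candidates[order[0]]
    return SelectionReport(candidate_ms=candidates, criterion_values=tuple(values),
                           chosen_m=chosen, method="bic")


def pca_eigenvalues(data: ExpressionDataset) -> np.ndarray:
    """Eigenvalues (descending) of the covariance matrix of the gene vectors.

    The covariance is taken across time between gene rows g_i; at most
    min(l, T-1) eigenvalues are nonzero. Computed via singular values of the
    row-centered data for numerical stability.
    """
    if data.n_times < 2:
        raise ValueError("need at least 2 time points")
    Yc = data.centered().values
    l, T = Yc.shape
    s = np.linalg.svd(Yc, compute_uv=False)
    lam = s ** 2 / (T - 1)
    k = min(l, T)
    out = np.zeros(k)
    out[: len(lam)] = lam
    if out[0] > 0:
        out[out < _EIG_ZERO_REL * out[0]] = 0.0
    return out


def select_m_pca(data: ExpressionDataset, fraction: float = 0.2) -> SelectionReport:
    """Smallest m whose residual eigenvalue mass fraction is <= ``fraction``."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    lam = pca_eigenvalues(data)
    total = lam.sum()
    if total <= 0.0:
        raise ValueError("all eigenvalues are zero: constant (degenerate) data")
    k = len(lam)
    residuals = tuple(float(lam[m:].sum() / total) for m in range(1, k + 1))
    chosen = next(m for m, r in zip(range(1, k + 1), residuals) if r <= fraction)
    return SelectionReport(candidate_ms=tuple(range(1, k + 1)),
                           criterion_values=residuals, chosen_m=chosen, method="pca")
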