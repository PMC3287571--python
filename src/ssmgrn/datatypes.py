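"""Core containers: model parameters and expression datasets.

The model is the linear-Gaussian state space model

    x_t = F x_{t-1} + w_t,   w_t ~ N(0, Q)
    y_t = H x_t   + v_t,     v_t ~ N(0, R)

with hidden states ``x_t`` of dimension ``m`` (the "hidden variables") and
observed expression profiles ``y_t`` of dimension ``l`` (one entry per gene).
The initial state is ``x_1 ~ N(mu0, Sigma0)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SSMParameters", "ExpressionDataset"]

_PSD_TOL = 1e-8


def _check_psd(A: np.ndarray, name: str) -> None:
    if not np.allclose(A, A.T, atol=_PSD_TOL):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (A + A.T))
    if w.min(initial=0.0) < -_PSD_TOL * max(1.0, abs(w).max(initial=0.0)):
        raise ValueError(f"{name} must be positive semi-definite (min eigenvalue {w.min()})")


@dataclass(frozen=True)
class SSMParameters:
    """Complete parameter set of a linear-Gaussian state space model.

    Parameters
    ----------
    F : (m, m) ndarray
        State transition matrix.
    H : (l, m) ndarray
        Observation (loading) matrix mapping hidden states to genes.
    Q : (m, m) ndarray
        State noise covariance, symmetric PSD.
    R : (l, l) ndarray
        Observation noise covariance. Estimation constrains it diagonal;
        simulation accepts any PSD matrix.
    mu0 : (m,) ndarray
        Initial state mean.
    Sigma0 : (m, m) ndarray
        Initial state covariance, symmetric PSD.
    """

    F: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    mu0: np.ndarray
    Sigma0: np.ndarray

    def __post_init__(self) -> None:
        for name in ("F", "H", "Q", "R", "mu0", "Sigma0"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        m = self.F.shape[0]
        l = self.H.shape[0]
        if m < 1:
            raise ValueError("hidden dimension m must be >= 1")
        if self.F.shape != (m, m):
            raise ValueError(f"F must be square, got {self.F.shape}")
        if self.H.shape != (l, m):
            raise ValueError(f"H must be (l, m)=({l}, {m}), got {self.H.shape}")
        if self.Q.shape != (m, m):
            raise ValueError(f"Q must be (m, m)=({m}, {m}), got {self.Q.shape}")
        if self.R.shape != (l, l):
            raise ValueError(f"R must be (l, l)=({l}, {l}), got {self.R.shape}")
        if self.mu0.shape != (m,):
            raise ValueError(f"mu0 must have shape ({m},), got {self.mu0.shape}")
        if self.Sigma0.shape != (m, m):
            raise ValueError(f"Sigma0 must be (m, m)=({m}, {m}), got {self.Sigma0.shape}")
        for name in ("Q", "R", "Sigma0"):
            _check_psd(getattr(self, name), name)
        if not np.all(np.isfinite(self.F)) or not np.all(np.isfinite(self.H)) \
                or not np.all(np.isfinite(self.mu0)):
            raise ValueError("parameters must be finite")

    @property
    def m(self) -> int:
        """Hidden-state dimension."""
        return self.F.shape[0]

    @property
    def l(self) -> int:
        """Observed (gene) dimension."""
        return self.H.shape[0]

    def rotate(self, U: np.ndarray) -> "SSMParameters":
        """Conjugate the latent space by an orthogonal matrix ``U`` (x -> U x).

        The transformed model has identical likelihood and connectivity
        matrix; the latent basis of the model is only identified up to such
        rotations.
        """
        U = np.asarray(U, dtype=float)
        if U.shape != (self.m, self.m) or not np.allclose(U @ U.T, np.eye(self.m), atol=1e-8):
            raise ValueError("U must be an orthogonal m x m matrix")
        return SSMParameters(
            F=U @ self.F @ U.T,
            H=self.H @ U.T,
            Q=U @ self.Q @ U.T,
            R=self.R,
            mu0=U @ self.mu0,
            Sigma0=U @ self.Sigma0 @ U.T,
        )


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes x time-points expression matrix with labels.

    ``values[i, t]`` is the expression of gene ``gene_ids[i]`` at time point
    ``time_labels[t]``. Rows are the gene vectors ``g_i`` of length ``T``.
    """

    values: np.ndarray
    gene_ids: tuple = field(default=None)
    time_labels: tuple = field(default=None)

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        l, T = values.shape
        gene_ids = self.gene_ids
        if gene_ids is None:
            gene_ids = tuple(f"g{i + 1}" for i in range(l))
        gene_ids = tuple(str(g) for g in gene_ids)
        time_labels = self.time_labels
        if time_labels is None:
            time_labels = tuple(f"t{t + 1}" for t in range(T))
        time_labels = tuple(str(t) for t in time_labels)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "time_labels", time_labels)
        if len(gene_ids) != l:
            raise ValueError(f"{len(gene_ids)} gene ids for {l} rows")
        if len(time_labels) != T:
            raise ValueError(f"{len(time_labels)} time labels for {T} columns")
        if len(set(gene_ids)) != l:
            dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite (no missing entries)")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def centered(self) -> "ExpressionDataset":
        """Return a copy with each gene row mean-centered across time."""
        return ExpressionDataset(
            self.values - self.values.mean(axis=1, keepdims=True),
            self.gene_ids,
            self.time_labels,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionDataset":
        """Build from a DataFrame with genes as the index, time points as columns."""
        return cls(df.to_numpy(dtype=float), tuple(df.index), tuple(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.time_labels))
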