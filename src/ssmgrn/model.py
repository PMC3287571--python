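"""High-level modelling interface.

``StateSpaceGRN`` wraps an expression dataset and a hidden dimension;
``fit()`` runs EM and returns a ``StateSpaceGRNResults`` carrying the
estimated parameters, the log-likelihood trace, BIC, and the network-level
readouts (connectivity matrix, edge calling, ROC against a gold standard).

    >>> model = StateSpaceGRN(dataset, m=2)
    >>> res = model.fit(seed=0)
    >>> net = res.infer_network(top_k=50)
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, SSMParameters
from .kalman import FilterSmootherResult, kalman_filter_smoother
from .network import ConnectivityMatrix, GeneNetwork, connectivity_matrix, \
    edges_by_threshold, edges_top_k
from .evaluation import EvaluationResult, ROCResult, roc_curve, score_network
from .selection import compute_bic, count_parameters
from .ssm import EMConfig, EMTrace, em_fit, simulate_ssm

__all__ = ["StateSpaceGRN", "StateSpaceGRNResults"]


class StateSpaceGRN:
    """Linear-Gaussian state space model of a gene expression time series.

    Parameters
    ----------
    data : ExpressionDataset or array-like
        l genes x T time points.
    m : int
        Hidden-state dimension, 1 <= m <= min(l, T).
    """

    def __init__(self, data, m: int = 2):
        if isinstance(data, pd.DataFrame):
            data = ExpressionDataset.from_dataframe(data)
        elif not isinstance(data, ExpressionDataset):
            data = ExpressionDataset(np.asarray(data, dtype=float))
        self.data = data
        if not 1 <= m <= min(data.n_genes, data.n_times):
            raise ValueError(
                f"m must be in [1, {min(data.n_genes, data.n_times)}], got {m}")
        self.m = int(m)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, m: int = 2) -> "StateSpaceGRN":
        return cls(ExpressionDataset.from_dataframe(df), m=m)

    @classmethod
    def from_tsv(cls, path, m: int = 2) -> "StateSpaceGRN":
        from .io import read_expression_tsv

        return cls(read_expression_tsv(path), m=m)

    def loglike(self, params: SSMParameters) -> float:
        """Marginal log-likelihood of the (centered) data under ``params``."""
        return kalman_filter_smoother(params, self.data.centered()).loglik

    def smooth(self, params: SSMParameters) -> FilterSmootherResult:
        """Exact filtered/smoothed moments of the centered data."""
        return kalman_filter_smoother(params, self.data.centered())

    def fit(self, max_iter: int = 500, tol: float = 1e-6, seed: int = 0,
            n_restarts: int = 1,
            init: SSMParameters | None = None) -> "StateSpaceGRNResults":
        config = EMConfig(max_iter=max_iter, tol=tol, seed=seed,
                          n_restarts=n_restarts)
        params, trace = em_fit(self.data, self.m, config, init=init)
        return StateSpaceGRNResults(self, params, trace)


class StateSpaceGRNResults:
    """Fit results: parameter estimates, likelihood diagnostics, networks."""

    def __init__(self, model: StateSpaceGRN, params: SSMParameters,
                 em_trace: EMTrace):
        self.model = model
        self.params = params
        self.em_trace = em_trace

    @property
    def llf(self) -> float:
        """Final marginal log-likelihood."""
        return self.em_trace.logliks[-1]

    @property
    def m(self) -> int:
        return self.params.m

    @property
    def n_params(self) -> int:
        return count_parameters(self.params.m, self.params.l)

    @property
    def bic(self) -> float:
        """Penalized log-likelihood (larger is better) with N = l*T."""
        n = self.model.data.n_genes * self.model.data.n_times
        return compute_bic(self.llf, self.n_params, n)

    def connectivity(self) -> ConnectivityMatrix:
        """Gene-level influence matrix C = H F (H'H)^{-1} H'."""
        return connectivity_matrix(self.params, gene_ids=self.model.data.gene_ids)

    def infer_network(self, top_k: int | None = None,
                      threshold: float | None = None) -> GeneNetwork:
        """Call edges from |C|, either the strongest ``top_k`` or all entries
        at or above ``threshold`` (exactly one must be given)."""
        if (top_k is None) == (threshold is None):
            raise ValueError("give exactly one of top_k or threshold")
        cm = self.connectivity()
        if top_k is not None:
            return edges_top_k(cm, top_k)
        return edges_by_threshold(cm, threshold)

    def score(self, truth: GeneNetwork, top_k: int | None = None,
              threshold: float | None = None) -> EvaluationResult:
        """Precision/recall of the inferred network against a gold standard."""
        return score_network(self.infer_network(top_k=top_k, threshold=threshold),
                             truth)

    def roc(self, truth: GeneNetwork) -> ROCResult:
        """ROC of |C_ij| as an edge score against a gold standard."""
        return roc_curve(self.connectivity(), truth)

    def simulate(self, T: int, seed: int = 0):
        """Simulate a new trajectory from the fitted parameters."""
        return simulate_ssm(self.params, T, seed)

    def save(self, path, meta: dict | None = None) -> None:
        from .io import write_model

        write_model(path, self.params, gene_ids=self.model.data.gene_ids,
                    meta=meta)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        d = self.model.data
        tr = self.em_trace
        lines = [
            "Linear-Gaussian state space model (EM fit)",
            "=" * 44,
            f"genes (l):            {d.n_genes}",
            f"time points (T):      {d.n_times}",
            f"hidden dimension (m): {self.m}",
            f"free parameters:      {self.n_params}",
            f"log-likelihood:       {self.llf:.4f}",
            f"BIC (max is best):    {self.bic:.4f}",
            f"EM iterations:        {tr.iterations}"
            f" ({'converged' if tr.converged else 'max_iter reached'})",
            f"restart used:         {tr.restart_index}",
        ]
        C = self.connectivity().C
        off = np.abs(C[~np.eye(C.shape[0], dtype=bool)])
        lines.append(f"|C| off-diagonal:     max {off.max():.4f}, "
                     f"median {np.median(off):.4f}")
        return "\n".join(lines)
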