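"""Scoring inferred networks against gold standards.

Precision is the fraction of inferred edges that are true (TP / inferred
edge count), recall the fraction of true edges recovered. ROC curves sweep
the threshold on |C_ij| over all ordered off-diagonal gene pairs; evaluation
is on unsigned directed edges (the weight's sign is ignored, direction must
match).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skmetrics

from .network import ConnectivityMatrix, GeneNetwork

__all__ = ["EvaluationResult", "ROCResult", "score_network", "roc_curve",
           "average_roc", "random_baseline_precision"]


@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float


@dataclass(frozen=True)
class ROCResult:
    """(FPR, TPR) points from (0,0) to (1,1) and the trapezoid AUROC."""

    points: tuple
    auroc: float


def score_network(inferred: GeneNetwork, truth: GeneNetwork) -> EvaluationResult:
    """Count directed-edge agreement between an inferred and a true network."""
    missing = set(inferred.genes) - set(truth.genes)
    if missing:
        raise ValueError(f"inferred genes not in truth: {sorted(missing)}")
    inf_pairs = inferred.edge_pairs
    true_pairs = truth.edge_pairs
    tp = len(inf_pairs & true_pairs)
    fp = len(inf_pairs - true_pairs)
    fn = len(true_pairs - inf_pairs)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return EvaluationResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)


def roc_curve(cm: ConnectivityMatrix, truth: GeneNetwork) -> ROCResult:
    """ROC of |C_ij| as an edge score over all ordered off-diagonal pairs.

    Thresholds sweep every distinct score; the curve starts at (0, 0) and
    ends at (1, 1). Requires the truth to contain both edges and non-edges
    among the candidate pairs.
    """
    genes = cm.gene_ids
    if set(genes) - set(truth.genes):
        raise ValueError("connectivity matrix genes not in truth network")
    true_pairs = truth.edge_pairs
    l = len(genes)
    y_true, scores = [], []
    for i in range(l):
        for j in range(l):
            if i == j:
                continue
            y_true.append((genes[j], genes[i]) in true_pairs)
            scores.append(abs(cm.C[i, j]))
    y_true = np.asarray(y_true)
    if y_true.all() or not y_true.any():
        raise ValueError("truth must contain both edges and non-edges among "
                         "candidate pairs")
    fpr, tpr, _ = _skmetrics.roc_curve(y_true, np.asarray(scores),
                                       drop_intermediate=False)
    auroc = _skmetrics.auc(fpr, tpr)
    return ROCResult(points=tuple(zip(fpr.tolist(), tpr.tolist())), auroc=float(auroc))


def average_roc(rocs, fpr_grid=None) -> ROCResult:
    """Average ROC curves pointwise on a common FPR grid.

    Each curve's TPR is linearly interpolated onto the grid (101 evenly
    spaced points by default) and averaged; the AUROC reported is that of
    the averaged curve.
    """
    rocs = list(rocs)
    if not rocs:
        raise ValueError("no ROC curves to average")
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(fpr_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0) or grid.min() < 0 or grid.max() > 1:
        raise ValueError("fpr_grid must be ascending within [0, 1]")
    tprs = []
    for roc in rocs:
        pts = np.asarray(roc.points)
        tprs.append(np.interp(grid, pts[:, 0], pts[:, 1]))
    mean_tpr = np.mean(tprs, axis=0)
    auroc = float(np.trapezoid(mean_tpr, grid))
    return ROCResult(points=tuple(zip(grid.tolist(), mean_tpr.tolist())), auroc=auroc)


def random_baseline_precision(truth: GeneNetwork, n_genes: int) -> float:
    """Expected precision of uniformly random edge guessing.

    Equals the edge density |true edges| / (n_genes * (n_genes - 1)) of the
    gold standard over ordered off-diagonal pairs.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    return truth.n_edges / (n_genes * (n_genes - 1))
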