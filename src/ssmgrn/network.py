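"""From fitted model parameters to a gene-level network.

The connectivity matrix C = H F (H'H)^{-1} H' projects the latent dynamics
back onto the genes: C[i][j] scores the influence of gene j on gene i, so an
entry with large |C_ij| is called as a directed edge gene_j -> gene_i.
C is invariant to orthogonal rotations of the latent space, which is what
makes it a usable summary of an otherwise non-identified latent basis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import SSMParameters

__all__ = ["ConnectivityMatrix", "GeneNetwork", "connectivity_matrix",
           "edges_by_threshold", "edges_top_k"]

CONVENTION = "C[i][j] = effect of gene j on gene i"

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Square gene-by-gene influence matrix with its label order."""

    C: np.ndarray
    gene_ids: tuple
    convention: str = CONVENTION

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        l = len(self.gene_ids)
        if C.shape != (l, l):
            raise ValueError(f"C must be ({l}, {l}), got {C.shape}")
        if not np.all(np.isfinite(C)):
            raise ValueError("C must be finite")


@dataclass(frozen=True)
class GeneNetwork:
    """Directed, weighted gene network without self-loops.

    ``edges`` maps (regulator, target) -> weight; each ordered pair appears
    at most once. Bidirectional pairs (i->j and j->i) are allowed.
    """

    genes: tuple
    edges: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        edges = {(str(a), str(b)): float(w) for (a, b), w in dict(self.edges).items()}
        object.__setattr__(self, "edges", edges)
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("duplicate gene labels")
        for reg, tgt in edges:
            if reg == tgt:
                raise ValueError(f"self-loop {reg}->{tgt} not allowed")
            if reg not in gene_set or tgt not in gene_set:
                raise ValueError(f"edge {reg}->{tgt} uses unknown gene label")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_pairs(self) -> frozenset:
        """Unweighted directed (regulator, target) pairs."""
        return frozenset(self.edges)

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.genes)
        for (reg, tgt), w in self.edges.items():
            G.add_edge(reg, tgt, weight=w)
        return G


def connectivity_matrix(params: SSMParameters, gene_ids=None) -> ConnectivityMatrix:
    """Compute C = H F (H'H)^{-1} H'.

    Falls back to the Moore-Penrose pseudo-inverse with a warning when H'H is
    ill-conditioned (condition number above 1e12).
    """
    H, F = params.H, params.F
    G = H.T @ H
    if np.linalg.cond(G) < _COND_LIMIT:
        C = H @ F @ np.linalg.solve(G, H.T)
    else:
        warnings.warn("H'H ill-conditioned; using pseudo-inverse", stacklevel=2)
        C = H @ F @ np.linalg.pinv(G) @ H.T
    if gene_ids is None:
        gene_ids = tuple(f"g{i + 1}" for i in range(params.l))
    return ConnectivityMatrix(C=C, gene_ids=tuple(gene_ids))


def _ranked_candidates(cm: ConnectivityMatrix):
    """Off-diagonal entries sorted by (|C| desc, row asc, col asc)."""
    C = cm.C
    l = C.shape[0]
    items = [(i, j) for i in range(l) for j in range(l) if i != j]
    items.sort(key=lambda ij: (-abs(C[ij[0], ij[1]]), ij[0], ij[1]))
    return items


def edges_by_threshold(cm: ConnectivityMatrix, th: float) -> GeneNetwork:
    """Call edge gene_j -> gene_i for every off-diagonal |C_ij| >= th."""
    if th < 0:
        raise ValueError("threshold must be >= 0")
    C, genes = cm.C, cm.gene_ids
    l = C.shape[0]
    edges = {}
    for i in range(l):
        for j in range(l):
            if i != j and abs(C[i, j]) >= th:
                edges[(genes[j], genes[i])] = C[i, j]
    return GeneNetwork(genes=genes, edges=edges)


def edges_top_k(cm: ConnectivityMatrix, k: int) -> GeneNetwork:
    """The k strongest off-diagonal entries as edges.

    Deterministic tie-break: larger |C| first, then smaller row index, then
    smaller column index.
    """
    l = len(cm.gene_ids)
    if not 0 <= k <= l * (l - 1):
        raise ValueError(f"k must be in [0, {l * (l - 1)}], got {k}")
    genes = cm.gene_ids
    edges = {}
    for i, j in _ranked_candidates(cm)[:k]:
        edges[(genes[j], genes[i])] = cm.C[i, j]
    return GeneNetwork(genes=genes, edges=edges)
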