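"""Plain-text file formats.

All files are tab-separated UTF-8 with ``.`` decimal separators and no
quoting. Genes are rows in expression files. Lines starting with ``#`` are
metadata comments (config hash, seed) and are ignored by the readers, so
every writer can embed its provenance without breaking round-trips.

Gold standards use the three-column regulator / target / flag dialect:
flag 1 rows are edges, flag 0 rows are explicit non-edges and are ignored.
Networks can also be exported as SIF (``regulator regulates target``) for
graph viewers.
"""
from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np

from .datatypes import ExpressionDataset, SSMParameters
from .network import GeneNetwork

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_goldstandard_tsv", "write_network", "read_network_tsv",
    "write_model", "read_model", "config_hash",
]

_FMT = "%.17g"  # round-trips IEEE doubles exactly


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _meta_lines(meta: dict | None):
    if not meta:
        return []
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    lines.append(f"# config_hash: {config_hash(meta)}")
    return lines


def write_expression_tsv(path, data: ExpressionDataset, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write("gene\t" + "\t".join(data.time_labels) + "\n")
        for i, g in enumerate(data.gene_ids):
            row = "\t".join(_FMT % v for v in data.values[i])
            fh.write(f"{g}\t{row}\n")


def read_expression_tsv(path) -> ExpressionDataset:
    """Read a genes x time-points table (first column gene IDs, header row
    of time labels). Rejects duplicate gene IDs, ragged rows and
    non-numeric cells with a located error message."""
    gene_ids, rows = [], []
    time_labels = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if time_labels is None:
                time_labels = fields[1:]
                if not time_labels:
                    raise ValueError(f"{path}: header row has no time labels")
                continue
            if len(fields) != len(time_labels) + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(time_labels) + 1} "
                    f"columns, got {len(fields)}")
            gene = fields[0]
            if gene in gene_ids:
                raise ValueError(f"{path}: line {lineno}: duplicate gene ID '{gene}'")
            vals = []
            for col, cell in enumerate(fields[1:], start=2):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}, column {col}: "
                        f"non-numeric cell '{cell}'") from None
            gene_ids.append(gene)
            rows.append(vals)
    if time_labels is None or not rows:
        raise ValueError(f"{path}: no data rows")
    return ExpressionDataset(np.asarray(rows), tuple(gene_ids), tuple(time_labels))


def read_goldstandard_tsv(path, genes=None) -> GeneNetwork:
    """Read a regulator / target / flag edge list.

    Rows with flag 0 are ignored; self-loop rows are skipped with a warning;
    a missing flag column counts as flag 1. ``genes`` extends the node set
    beyond genes that appear in edges.
    """
    edges = {}
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}: line {lineno}: expected 2-3 columns, "
                                 f"got {len(fields)}")
            reg, tgt = fields[0], fields[1]
            if len(fields) == 3:
                if fields[2] not in ("0", "1"):
                    raise ValueError(f"{path}: line {lineno}: flag must be 0 or 1, "
                                     f"got '{fields[2]}'")
                if fields[2] == "0":
                    seen.update((reg, tgt))
                    continue
            if reg == tgt:
                warnings.warn(f"{path}: line {lineno}: skipping self-loop "
                              f"{reg}->{tgt}", stacklevel=2)
                seen.add(reg)
                continue
            edges[(reg, tgt)] = 1.0
            seen.update((reg, tgt))
    all_genes = list(genes) if genes is not None else sorted(seen)
    for g in sorted(seen):
        if g not in all_genes:
            all_genes.append(g)
    return GeneNetwork(genes=tuple(all_genes), edges=edges)


def write_network(path, network: GeneNetwork, format: str = "tsv",
                  meta: dict | None = None) -> None:
    """Write a network as gold-standard TSV or SIF, rows sorted by
    (regulator, target) for deterministic output."""
    pairs = sorted(network.edges)
    with open(path, "w", encoding="utf-8") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        if format == "tsv":
            for reg, tgt in pairs:
                fh.write(f"{reg}\t{tgt}\t1\n")
        elif format == "sif":
            for reg, tgt in pairs:
                fh.write(f"{reg} regulates {tgt}\n")
        else:
            raise ValueError(f"unknown network format '{format}'")


def read_network_tsv(path, genes=None) -> GeneNetwork:
    """Alias for :func:`read_goldstandard_tsv` (same dialect)."""
    return read_goldstandard_tsv(path, genes=genes)


def write_model(path, params: SSMParameters, gene_ids=None,
                meta: dict | None = None) -> None:
    """Write a fitted model as a single diffable text document, one named
    block per matrix."""
    blocks = [("F", params.F), ("H", params.H), ("Q", params.Q),
              ("R", params.R), ("mu0", params.mu0.reshape(1, -1)),
              ("Sigma0", params.Sigma0)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ssmgrn model v1\n")
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write(f"m\t{params.m}\n")
        fh.write(f"l\t{params.l}\n")
        if gene_ids is not None:
            fh.write("genes\t" + "\t".join(gene_ids) + "\n")
        for name, M in blocks:
            fh.write(f"[{name}]\n")
            for row in np.atleast_2d(M):
                fh.write("\t".join(_FMT % v for v in row) + "\n")


def read_model(path):
    """Read a model document; returns ``(SSMParameters, gene_ids or None)``."""
    blocks: dict[str, list] = {}
    gene_ids = None
    current = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                blocks[current] = []
                continue
            if current is None:
                key, *rest = line.split("\t")
                if key == "genes":
                    gene_ids = tuple(rest)
                continue
            blocks[current].append([float(v) for v in line.split("\t")])
    try:
        params = SSMParameters(
            F=np.asarray(blocks["F"]), H=np.asarray(blocks["H"]),
            Q=np.asarray(blocks["Q"]), R=np.asarray(blocks["R"]),
            mu0=np.asarray(blocks["mu0"]).ravel(),
            Sigma0=np.asarray(blocks["Sigma0"]))
    except KeyError as exc:
        raise ValueError(f"{path}: missing model block {exc}") from None
    return params, gene_ids
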