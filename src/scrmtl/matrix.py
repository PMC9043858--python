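"""Count and expression matrix containers.

Cells are rows and genes are columns everywhere inside the package; the
10x-style gene-major layout is transposed at the file-reader boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp


def _check_ids(ids: list[str], n: int, what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(ids) != n:
        raise ValueError(f"{what}: expected {n} identifiers, got {len(ids)}")
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"{what}: duplicate identifiers {sorted(set(dups))[:5]}")
    return ids


def _as_dense(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values)


@dataclass
class CountMatrix:
    """Non-negative integer counts, cells x genes, with identifiers."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        v = _as_dense(self.values)
        if v.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {v.shape}")
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ValueError(f"counts must have >=1 cell and >=1 gene, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("counts contain negative entries")
        if not np.issubdtype(v.dtype, np.integer):
            frac = v != np.floor(v)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise ValueError(
                    f"counts contain non-integer entry {v[i, j]!r} at cell row {i}, gene column {j}"
                )
            v = v.astype(np.int64)
        self.values = v
        self.cell_ids = _check_ids(self.cell_ids, v.shape[0], "cell_ids")
        self.gene_ids = _check_ids(self.gene_ids, v.shape[1], "gene_ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        """Restrict to the cells/genes selected by boolean masks."""
        v = self.values
        cells = self.cell_ids
        genes = self.gene_ids
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask, dtype=bool)
            v = v[cell_mask]
            cells = [c for c, keep in zip(cells, cell_mask) if keep]
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask, dtype=bool)
            v = v[:, gene_mask]
            genes = [g for g, keep in zip(genes, gene_mask) if keep]
        return CountMatrix(v, cells, genes)


@dataclass
class ExpressionMatrix:
    """Normalized log-expression, cells x genes, with processing provenance."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(_as_dense(self.values), dtype=float)
        if v.ndim != 2:
            raise ValueError(f"expression must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression contains non-finite entries")
        self.values = v
        self.cell_ids = _check_ids(self.cell_ids, v.shape[0], "cell_ids")
        self.gene_ids = _check_ids(self.gene_ids, v.shape[1], "gene_ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]
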