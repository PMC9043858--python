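"""Quality control, filtering, normalization and log transform.

The pipeline turns a raw count matrix into a model-ready expression
matrix in four steps, in this order:

1. *Good cells*: a cell is kept when strictly more than
   ``min_genes_per_good_cell`` genes have a non-zero count in it
   (default: more than 1000).
2. *Expressed genes*: evaluated over the good cells only — a gene is
   kept when its count strictly exceeds ``min_count_expressed``
   (default 5) in at least ``min_fraction_good_cells`` (default 10%,
   inclusive) of the good cells.
3. *Normalization*: by default each cell is scaled so its library size
   (total count) equals the median library size across cells.  The step
   is pluggable via the ``method`` enum so an alternative transform can
   be swapped in; ``none`` leaves counts untouched.
4. *Log transform*: ``log2(x + 1)``.

Boundary semantics are deliberate: "more than" and "exceeds" are strict
inequalities, "at least" is inclusive.  Good cells are determined from
the raw matrix and are not recomputed after gene filtering (no
fixed-point iteration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import CountMatrix, ExpressionMatrix

NORMALIZE_METHODS = ("library_size", "none")


@dataclass
class QCThresholds:
    """Thresholds for the good-cell and expressed-gene filters."""

    min_genes_per_good_cell: int = 1000
    min_count_expressed: int = 5
    min_fraction_good_cells: float = 0.10

    def __post_init__(self) -> None:
        if self.min_genes_per_good_cell < 0 or self.min_count_expressed < 0:
            raise ValueError("integer QC thresholds must be >= 0")
        if not 0.0 <= self.min_fraction_good_cells <= 1.0:
            raise ValueError(
                f"min_fraction_good_cells must be in [0, 1], got {self.min_fraction_good_cells}"
            )


def identify_good_cells(counts: CountMatrix, thresholds: QCThresholds | None = None) -> np.ndarray:
    """Boolean mask over cells: strictly more than the threshold genes detected.

    A gene counts as detected in a cell when its count is non-zero.
    """
    thresholds = thresholds or QCThresholds()
    n_detected = np.count_nonzero(counts.values > 0, axis=1)
    return n_detected > thresholds.min_genes_per_good_cell


def identify_expressed_genes(
    counts: CountMatrix,
    good_mask: np.ndarray,
    thresholds: QCThresholds | None = None,
) -> np.ndarray:
    """Boolean mask over genes, evaluated over the good cells only.

    Gene j is expressed iff the fraction of good cells in which its
    count strictly exceeds ``min_count_expressed`` is at least
    ``min_fraction_good_cells``.
    """
    thresholds = thresholds or QCThresholds()
    good_mask = np.asarray(good_mask, dtype=bool)
    if good_mask.shape != (counts.n_cells,):
        raise ValueError(
            f"good_mask length {good_mask.shape} does not match {counts.n_cells} cells"
        )
    n_good = int(good_mask.sum())
    if n_good == 0:
        raise ValueError("no good cells: cannot evaluate expressed-gene fractions")
    sub = counts.values[good_mask]
    frac = np.count_nonzero(sub > thresholds.min_count_expressed, axis=0) / n_good
    return frac >= thresholds.min_fraction_good_cells


def normalize(filtered: CountMatrix, method: str = "library_size") -> np.ndarray:
    """Scale each cell's counts to the median library size (or pass through)."""
    if method not in NORMALIZE_METHODS:
        raise ValueError(f"unknown normalization method {method!r}; choose from {NORMALIZE_METHODS}")
    values = filtered.values.astype(float)
    if method == "none":
        return values
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        idx = int(np.argwhere(totals == 0)[0, 0])
        raise ValueError(
            f"cell {filtered.cell_ids[idx]!r} has zero total count; "
            "zero-library cells must be filtered before normalization"
        )
    target = float(np.median(totals))
    return values * (target / totals)[:, None]


def log_transform(matrix: np.ndarray) -> np.ndarray:
    """Element-wise log2(x + 1); rejects negative input."""
    m = np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise ValueError("log_transform requires non-negative entries")
    return np.log2(m + 1.0)


def preprocess_pipeline(
    counts: CountMatrix,
    thresholds: QCThresholds | None = None,
    method: str = "library_size",
) -> ExpressionMatrix:
    """Full pipeline: good cells -> expressed genes -> normalize -> log2(x+1)."""
    thresholds = thresholds or QCThresholds()
    good = identify_good_cells(counts, thresholds)
    if not good.any():
        raise ValueError(
            "all cells removed by the good-cell filter "
            f"(threshold: > {thresholds.min_genes_per_good_cell} detected genes)"
        )
    expressed = identify_expressed_genes(counts, good, thresholds)
    if not expressed.any():
        raise ValueError(
            "all genes removed by the expressed-gene filter "
            f"(threshold: count > {thresholds.min_count_expressed} in >= "
            f"{thresholds.min_fraction_good_cells:.0%} of good cells)"
        )
    kept = counts.subset(cell_mask=good, gene_mask=expressed)
    values = log_transform(normalize(kept, method))
    return ExpressionMatrix(
        values,
        kept.cell_ids,
        kept.gene_ids,
        provenance={
            "good_cell_mask": good.tolist(),
            "expressed_gene_mask": expressed.tolist(),
            "normalize_method": method,
            "thresholds": {
                "min_genes_per_good_cell": thresholds.min_genes_per_good_cell,
                "min_count_expressed": thresholds.min_count_expressed,
                "min_fraction_good_cells": thresholds.min_fraction_good_cells,
            },
        },
    )
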