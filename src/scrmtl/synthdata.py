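"""Gamma-Poisson scRNA-seq count simulator with group DE and dropout.

A simplified Splat-style hierarchical generator:

* baseline gene means ~ Gamma(shape, rate);
* cells assigned to groups by a multinomial over ``group_probs``;
* per group, a fraction ``de_prob`` of genes is differentially
  expressed, each scaled by a log-normal factor, inverted (reciprocal)
  with probability 0.5 so both up- and down-regulation occur;
* per-cell library sizes ~ log-normal; the expected count of gene j in
  cell i is the cell's library size times the group's normalized mean
  profile;
* observed counts ~ Poisson(expected);
* dropout zeroes each entry independently with probability
  ``logistic(dropout_shape * (log(expected) - dropout_mid))``; the
  midpoint is calibrated by bisection so the expected fraction of extra
  zeros (entries zeroed that would otherwise be non-zero) matches
  ``dropout_rate_target``.

Batch effects and mean-variance (BCV) inflation of the full Splat model
are deliberately omitted: the simulation configurations this generator
emulates do not exercise them.  Presets data1–data4 fix 2000 genes,
equal group probabilities and dropout rate 0.2, varying cells/groups as
500/2, 1000/3, 1500/4, 2000/5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import expit

from .matrix import CountMatrix

PRESETS = {
    "data1": (2000, 500, 2),
    "data2": (2000, 1000, 3),
    "data3": (2000, 1500, 4),
    "data4": (2000, 2000, 5),
}


@dataclass
class SimConfig:
    n_cells: int = 500
    n_genes: int = 2000
    n_groups: int = 2
    group_probs: tuple[float, ...] | None = None  # None -> equal
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_location: float = 11.0
    libsize_scale: float = 0.2
    de_prob: float = 0.1
    de_facLoc: float = 0.1
    de_facScale: float = 0.4
    dropout_mid: float | None = None  # None -> calibrated to the target rate
    dropout_shape: float = -1.0
    dropout_rate_target: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1 or self.n_groups < 1:
            raise ValueError("n_cells, n_genes and n_groups must be >= 1")
        if self.group_probs is None:
            self.group_probs = tuple([1.0 / self.n_groups] * self.n_groups)
        probs = tuple(float(p) for p in self.group_probs)
        if len(probs) != self.n_groups:
            raise ValueError(f"{len(probs)} group probabilities for {self.n_groups} groups")
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("group_probs must be non-negative and sum to 1")
        self.group_probs = probs
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate_target < 1.0:
            raise ValueError("dropout_rate_target must lie in [0, 1)")


@dataclass
class SimResult:
    counts: CountMatrix
    labels: list[str]
    truth: dict[str, Any] = field(default_factory=dict)


def preset(name: str) -> SimConfig:
    """Named simulation configurations data1–data4."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    n_genes, n_cells, n_groups = PRESETS[name]
    return SimConfig(
        n_cells=n_cells, n_genes=n_genes, n_groups=n_groups, dropout_rate_target=0.2
    )


def _calibrate_dropout_mid(log_lam: np.ndarray, nonzero_prob: np.ndarray,
                           shape: float, target: float) -> float:
    """Bisect the logistic midpoint so E[extra-zero fraction] = target.

    The expected extra-zero fraction is mean over entries of
    P(drop) * P(count would be non-zero).  With negative shape the
    dropout probability is increasing in the midpoint, so bisection on
    the midpoint is monotone.
    """

    def expected(mid: float) -> float:
        return float(np.mean(expit(shape * (log_lam - mid)) * nonzero_prob))

    lo, hi = -60.0, 60.0
    if expected(hi) < target:  # cannot reach target even with all-drop
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate(config: SimConfig | None = None) -> SimResult:
    """Draw one synthetic labeled count matrix from the generative model."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    base_means = rng.gamma(cfg.mean_shape, 1.0 / cfg.mean_rate, size=cfg.n_genes)
    groups = rng.choice(cfg.n_groups, size=cfg.n_cells, p=np.asarray(cfg.group_probs))

    de_factors = np.ones((cfg.n_groups, cfg.n_genes))
    for g in range(cfg.n_groups):
        de_mask = rng.random(cfg.n_genes) < cfg.de_prob
        n_de = int(de_mask.sum())
        fac = rng.lognormal(cfg.de_facLoc, cfg.de_facScale, size=n_de)
        invert = rng.random(n_de) < 0.5
        fac[invert] = 1.0 / fac[invert]
        de_factors[g, de_mask] = fac

    group_means = base_means[None, :] * de_factors
    profiles = group_means / group_means.sum(axis=1, keepdims=True)
    lib_sizes = rng.lognormal(cfg.libsize_location, cfg.libsize_scale, size=cfg.n_cells)

    lam = lib_sizes[:, None] * profiles[groups]
    counts = rng.poisson(lam)
    predrop_counts = counts

    dropout_mask = np.zeros_like(counts, dtype=bool)
    mid = cfg.dropout_mid
    if cfg.dropout_rate_target > 0 or mid is not None:
        log_lam = np.log(lam + 1e-300)
        if mid is None:
            mid = _calibrate_dropout_mid(
                log_lam, -np.expm1(-lam), cfg.dropout_shape, cfg.dropout_rate_target
            )
        p_drop = expit(cfg.dropout_shape * (log_lam - mid))
        dropout_mask = rng.random(counts.shape) < p_drop
        counts = np.where(dropout_mask, 0, counts)

    n_digits = len(str(cfg.n_cells))
    cell_ids = [f"cell{str(i + 1).zfill(n_digits)}" for i in range(cfg.n_cells)]
    gene_ids = [f"gene{str(j + 1).zfill(len(str(cfg.n_genes)))}" for j in range(cfg.n_genes)]
    labels = [f"group{g + 1}" for g in groups]

    return SimResult(
        counts=CountMatrix(counts, cell_ids, gene_ids),
        labels=labels,
        truth={
            "base_means": base_means,
            "de_factors": de_factors,
            "group_assignments": groups,
            "lib_sizes": lib_sizes,
            "dropout_mask": dropout_mask,
            "dropout_mid": mid,
            "extra_zero_fraction": float(np.mean(dropout_mask & (predrop_counts > 0))),
            "expected_counts": lam,
        },
    )
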