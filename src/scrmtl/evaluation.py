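"""Evaluation protocols: repeated splits, training-size curves, per-class
recall/precision, k-fold cross-validation stability, Wilcoxon rank-sum.

The protocols mirror the standard supervised cell-typing benchmark:
an 80/20 train/test split; training-set subsampling at 20–100% in steps
of 20% with accuracy mean ± sd over repeated runs; per-class recall and
precision; and a 10-fold CV in which each fold's training part is
repeatedly re-split 9:1 to measure validation-accuracy stability, with
fold medians compared by a Wilcoxon rank-sum test.

Splits are stratified by class by default.  Plain random splitting can
drop rare cell types from either side; stratification is the package's
default deviation and can be disabled per call.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .celltyper import LabeledDataset, accuracy, predict, train
from .matrix import ExpressionMatrix
from .rmtl import RMTLConfig


@dataclass
class EvalConfig:
    test_fraction: float = 0.2
    subsample_rates: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    n_runs: int = 100
    cv_folds: int = 10
    inner_train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1 or not 0 < self.inner_train_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")
        rates = tuple(float(r) for r in self.subsample_rates)
        if any(not 0 < r <= 1 for r in rates) or list(rates) != sorted(rates):
            raise ValueError("subsample_rates must be in (0, 1] and ascending")
        self.subsample_rates = rates
        if self.n_runs < 1 or self.cv_folds < 2:
            raise ValueError("n_runs >= 1 and cv_folds >= 2 required")


@dataclass
class EvalReport:
    """Container for protocol outputs; every accuracy lies in [0, 1]."""

    subsample: dict = field(default_factory=dict)  # rate -> {mean, sd, accuracies}
    per_class: dict = field(default_factory=dict)  # class -> {recall, precision}
    confusion: dict = field(default_factory=dict)
    cv_validation: list = field(default_factory=list)  # folds x runs
    cv_test: list = field(default_factory=list)  # one per fold
    cv_fold_medians: list = field(default_factory=list)
    wilcoxon_p: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subsample": self.subsample,
            "per_class": self.per_class,
            "confusion": self.confusion,
            "cv_validation": self.cv_validation,
            "cv_test": self.cv_test,
            "cv_fold_medians": self.cv_fold_medians,
            "wilcoxon_p": self.wilcoxon_p,
        }


# ---------------------------------------------------------------------------
# splitting


def _subset(data: LabeledDataset, idx: np.ndarray) -> LabeledDataset:
    e = data.expr
    return LabeledDataset(
        ExpressionMatrix(
            e.values[idx],
            [e.cell_ids[i] for i in idx],
            e.gene_ids,
            provenance=e.provenance,
        ),
        [data.labels[i] for i in idx],
    )


def _split_indices(
    labels: list[str], test_fraction: float, rng: np.random.Generator, stratified: bool
) -> tuple[np.ndarray, np.ndarray]:
    n = len(labels)
    if stratified:
        train_idx, test_idx = [], []
        arr = np.asarray(labels)
        for cls in sorted(set(labels)):
            idx = np.flatnonzero(arr == cls)
            if len(idx) == 1:
                warnings.warn(
                    f"class {cls!r} has a single cell; assigned to training", stacklevel=3
                )
                train_idx.extend(idx)
                continue
            perm = rng.permutation(idx)
            n_test = int(round(len(idx) * test_fraction))
            n_test = min(max(n_test, 1), len(idx) - 1)
            test_idx.extend(perm[:n_test])
            train_idx.extend(perm[n_test:])
        return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def split_train_test(
    data: LabeledDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive (seeded) train/test split; stratified by default."""
    if data.expr.n_cells < 2:
        raise ValueError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    tr, te = _split_indices(data.labels, test_fraction, rng, stratified)
    return _subset(data, tr), _subset(data, te)


def _stratified_subsample(
    labels: list[str], rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-class subsample keeping at least one cell per class."""
    arr = np.asarray(labels)
    keep: list[np.ndarray] = []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(arr == cls)
        k = max(1, int(round(len(idx) * rate)))
        keep.append(rng.permutation(idx)[:k])
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# protocols


def subsample_curve(
    data: LabeledDataset,
    eval_config: EvalConfig | None = None,
    rmtl_config: RMTLConfig | None = None,
) -> dict:
    """Accuracy mean ± sd per training-subsample rate over repeated runs.

    Per run and rate: a fresh stratified 80/20 split, the training set
    subsampled to the rate, a model fit, and test accuracy recorded.
    """
    ec = eval_config or EvalConfig()
    rc = rmtl_config or RMTLConfig()
    out: dict = {}
    for rate in ec.subsample_rates:
        accs = []
        for run in range(ec.n_runs):
            seed = int(
                np.random.SeedSequence([ec.seed, int(rate * 1000), run]).generate_state(1)[0]
                % 2**31
            )
            tr, te = split_train_test(data, ec.test_fraction, seed=seed)
            if rate < 1.0:
                rng = np.random.default_rng(seed + 1)
                keep = _stratified_subsample(tr.labels, rate, rng)
                tr = _subset(tr, keep)
            model, cmap = train(tr, rc)
            accs.append(accuracy(te.labels, predict(model, cmap, te.expr)))
        out[rate] = {
            "mean": float(np.mean(accs)),
            "sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "accuracies": [float(a) for a in accs],
        }
    return out


def class_metrics(true_labels: list[str], predicted_labels: list[str]) -> tuple[dict, dict]:
    """Per-class recall and precision plus the confusion matrix.

    A class never predicted gets precision None (undefined), not a
    division error.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    t = np.asarray([str(x) for x in true_labels])
    p = np.asarray([str(x) for x in predicted_labels])
    classes = sorted(set(t) | set(p))
    confusion = {
        ct: {cp: int(np.sum((t == ct) & (p == cp))) for cp in classes} for ct in classes
    }
    metrics = {}
    for c in classes:
        tp = int(np.sum((t == c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        fp = int(np.sum((t != c) & (p == c)))
        recall = tp / (tp + fn) if (tp + fn) > 0 else None
        precision = tp / (tp + fp) if (tp + fp) > 0 else None
        metrics[c] = {"recall": recall, "precision": precision}
    return metrics, confusion


def cv_stability(
    data: LabeledDataset,
    eval_config: EvalConfig | None = None,
    rmtl_config: RMTLConfig | None = None,
) -> EvalReport:
    """Outer k-fold CV with repeated 9:1 inner splits per fold.

    Each fold yields ``n_runs`` validation accuracies (model fit on the
    inner 90%, scored on the inner 10%) and one test accuracy (model fit
    on the fold's full training part, scored on the held-out part).
    Fold medians of the validation accuracies summarize stability.
    """
    ec = eval_config or EvalConfig()
    rc = rmtl_config or RMTLConfig()
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=ec.cv_folds, shuffle=True, random_state=ec.seed)
    report = EvalReport()
    labels_arr = np.asarray(data.labels)
    for fold, (tr_idx, te_idx) in enumerate(skf.split(data.expr.values, labels_arr)):
        tr = _subset(data, tr_idx)
        te = _subset(data, te_idx)
        fold_val = []
        for run in range(ec.n_runs):
            seed = int(
                np.random.SeedSequence([ec.seed, fold, run]).generate_state(1)[0] % 2**31
            )
            inner_tr, inner_val = split_train_test(
                tr, test_fraction=1.0 - ec.inner_train_fraction, seed=seed
            )
            model, cmap = train(inner_tr, rc)
            fold_val.append(accuracy(inner_val.labels, predict(model, cmap, inner_val.expr)))
        model, cmap = train(tr, rc)
        report.cv_validation.append([float(a) for a in fold_val])
        report.cv_test.append(accuracy(te.labels, predict(model, cmap, te.expr)))
        report.cv_fold_medians.append(float(np.median(fold_val)))
    return report


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _rank_with_ties(combined: np.ndarray) -> np.ndarray:
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(len(combined))
    sorted_vals = combined[order]
    i = 0
    while i < len(combined):
        j = i
        while j + 1 < len(combined) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # mid-rank, 1-based
        i = j + 1
    return ranks


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of rank assignments when the combined sample size
    is at most 12 and there are no ties; normal approximation with tie
    correction otherwise.  Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    combined = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    n = n1 + n2
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = len(np.unique(combined)) < n
    use_exact = mode == "exact" or (mode == "auto" and n <= 12 and not has_ties)
    ranks = _rank_with_ties(combined)
    W = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    if use_exact:
        if has_ties:
            raise ValueError("exact mode requires tie-free samples")
        dev = abs(W - mu)
        total = math.comb(n, n1)
        count = 0
        for comb in itertools.combinations(range(1, n + 1), n1):
            if abs(sum(comb) - mu) >= dev - 1e-12:
                count += 1
        return count / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (W - mu) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))
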