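"""One-vs-rest cell typing on top of the multi-task learner.

Each cell type becomes one binary task ("is this cell of type t?") over
the shared expression matrix; prediction assigns each query cell the
class whose task score is maximal (ties break toward the lowest task
index, i.e. lexicographically first class name).  No rejection option:
every query cell receives one of the training classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix
from .rmtl import RMTLConfig, RMTLModel, TaskData, fit, predict_scores


@dataclass
class LabeledDataset:
    """Expression matrix plus per-cell class labels (aligned to cell order)."""

    expr: ExpressionMatrix
    labels: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.expr.n_cells:
            raise ValueError(
                f"{len(self.labels)} labels for {self.expr.n_cells} cells"
            )

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))


@dataclass
class ClassMap:
    """Bijection between task indices and class names (lexicographic order)."""

    classes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class names must be unique")
        self.classes = sorted(self.classes)

    def index_of(self, name: str) -> int:
        return self.classes.index(name)

    def __len__(self) -> int:
        return len(self.classes)


def build_tasks(data: LabeledDataset) -> tuple[list[TaskData], ClassMap]:
    """One binary ±1 task per class over the shared design matrix."""
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("one-vs-rest undefined with a single class")
    class_map = ClassMap(classes)
    X = data.expr.values
    labels = np.asarray(data.labels)
    tasks = []
    for name in class_map.classes:
        y = np.where(labels == name, 1.0, -1.0)
        tasks.append(TaskData(X, y, task_name=name))
    return tasks, class_map


def train(data: LabeledDataset, config: RMTLConfig | None = None) -> tuple[RMTLModel, ClassMap]:
    """Build one-vs-rest tasks and fit the multi-task model."""
    tasks, class_map = build_tasks(data)
    model = fit(tasks, config)
    return model, class_map


def align_genes(model_genes: list[str], query: ExpressionMatrix) -> ExpressionMatrix:
    """Reorder a query matrix to the training gene order.

    Genes absent from the query are imputed as 0 (log scale) with a
    warning; extra query genes are dropped.  Errors when the overlap is
    empty.
    """
    pos = {g: j for j, g in enumerate(query.gene_ids)}
    hit = [g for g in model_genes if g in pos]
    if not hit:
        raise ValueError("no overlap between model genes and query genes")
    out = np.zeros((query.n_cells, len(model_genes)))
    missing = 0
    for j, g in enumerate(model_genes):
        if g in pos:
            out[:, j] = query.values[:, pos[g]]
        else:
            missing += 1
    if missing:
        warnings.warn(
            f"{missing} of {len(model_genes)} model genes absent from query; imputed as 0",
            stacklevel=2,
        )
    return ExpressionMatrix(
        out, query.cell_ids, list(model_genes),
        provenance={**query.provenance, "aligned_missing_genes": missing},
    )


def predict(model: RMTLModel, class_map: ClassMap, expr: ExpressionMatrix) -> list[str]:
    """Predicted class per cell: argmax over task decision scores."""
    if expr.n_genes != model.n_features:
        raise ValueError(
            f"query has {expr.n_genes} genes but the model expects "
            f"{model.n_features}; align with align_genes first"
        )
    scores = predict_scores(model, expr.values)
    idx = np.argmax(scores, axis=1)  # first maximum on exact ties
    return [class_map.classes[i] for i in idx]


def accuracy(true_labels: list[str], predicted_labels: list[str]) -> float:
    """Fraction of cells whose predicted class equals the true class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    return float(np.mean(np.asarray(true_labels) == np.asarray(predicted_labels)))
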