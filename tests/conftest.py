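import numpy as np
import pytest

from scrmtl import (
    CountMatrix,
    LabeledDataset,
    QCThresholds,
    SimConfig,
    preprocess_pipeline,
    simulate,
)

# 6 cells x 3 genes worked example: under the default count>5 / >=10% gene
# thresholds (all cells treated as good), genes 1 and 3 survive, gene 2 not.
TOY_VALUES = np.array(
    [[6, 0, 9], [7, 0, 9], [6, 1, 9], [0, 2, 9], [0, 3, 9], [0, 5, 9]]
)


@pytest.fixture
def toy_counts() -> CountMatrix:
    return CountMatrix(
        TOY_VALUES.copy(),
        [f"c{i}" for i in range(6)],
        ["g1", "g2", "g3"],
    )


def labeled_from_sim(result, min_genes=50) -> LabeledDataset:
    """Preprocess a simulation and align its labels to the kept cells."""
    expr = preprocess_pipeline(
        result.counts, QCThresholds(min_genes_per_good_cell=min_genes)
    )
    lab = dict(zip(result.counts.cell_ids, result.labels))
    return LabeledDataset(expr, [lab[c] for c in expr.cell_ids])


@pytest.fixture(scope="session")
def sim_dataset() -> LabeledDataset:
    """Small, well-separated 3-group dataset used across protocol tests."""
    result = simulate(
        SimConfig(n_cells=180, n_genes=300, n_groups=3, de_facLoc=1.0, seed=11)
    )
    return labeled_from_sim(result)


def random_tasks(rng, T, n, p, noise=0.3):
    """Random separable-ish binary tasks for solver tests."""
    from scrmtl import TaskData

    tasks = []
    for t in range(T):
        X = rng.normal(size=(n, p))
        w = rng.normal(size=p)
        y = np.where(X @ w + noise * rng.normal(size=n) > 0, 1.0, -1.0)
        if len(np.unique(y)) < 2:
            y[0] *= -1
        tasks.append(TaskData(X, y, task_name=f"t{t}"))
    return tasks
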