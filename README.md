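# scrmtl

Supervised cell-type classification for single-cell RNA-seq count data by
**regularized multi-task learning** (RMTL), with the surrounding pipeline:
quality control and normalization, one-vs-rest task construction, repeated
split / subsampling / cross-validation evaluation protocols, and a
gamma-Poisson count simulator so that the whole system can be exercised
without any external download.

## Who this is for

Annotating cell types by clustering followed by manual marker-gene lookup is
slow and biased toward prior knowledge. When a labeled reference experiment
exists, a supervised classifier can type the cells of a query experiment
automatically. `scrmtl` treats the recognition of each cell type as its own
binary task ("is this cell of type *t*?") and trains all tasks *jointly*, so
that information shared between related cell populations is exploited rather
than ignored.

## The model

Given a reference expression matrix with cells from `T` types, each task `t`
is a binary problem with labels `y ∈ {+1, −1}` over the shared gene space.
The task weight vectors are coupled by regularization. In the default
*shared-offset* mode each task's linear model decomposes as

    w_t = w0 + v_t

and the fit minimizes

    Σ_t L_t(w0 + v_t, b_t)  +  λ1 ‖w0‖²  +  λ2 Σ_t ‖v_t‖²

where `L_t` is the mean logistic (or squared-hinge) loss of task `t`,
`λ1` penalizes the shared component and `λ2` controls task relatedness:
`λ2 → ∞` collapses every task onto one pooled model, `λ1 → ∞` decouples the
tasks completely. The alternative *L2,1* mode penalizes the stacked weight
matrix `W` (tasks × genes) by

    Σ_t L_t(w_t, b_t)  +  λ1 ‖W‖₂,₁  +  λ2 ‖W‖²_F

where the L2,1 norm sums, over genes, the Euclidean norm of each gene's
weights across tasks — joint feature selection that switches a gene on or
off for all cell types at once.

Both objectives are convex and are solved by monotone FISTA (accelerated
proximal gradient with backtracking line search); all penalties are handled
exactly in closed-form proximal steps, so the solver stays well conditioned
at extreme λ. A query cell is assigned the class with the maximal task
decision score.

## Worked example

Simulate the 500-cell / 2-group / 2,000-gene configuration with 20% dropout,
preprocess it, train, and run the subsampling protocol (3 runs per rate):

```sh
scrmtl simulate --preset data1 --seed 7 --out-counts counts.tsv --out-labels labels.tsv
scrmtl preprocess --counts counts.tsv --out expr.tsv
scrmtl train --expr expr.tsv --labels labels.tsv --lambda1 0.1 --lambda2 0.1 \
             --seed 7 --model-out model.json
scrmtl evaluate --expr expr.tsv --labels labels.tsv --protocol subsample \
                --runs 3 --seed 7 --lambda1 0.1 --lambda2 0.1 --report report.json
```

Each command prints a one-line JSON summary, e.g. for the steps above:

```
{"status": "ok", "command": "simulate",   "seed": 7, "n_cells": 500, "n_genes": 2000, ...}
{"status": "ok", "command": "preprocess", "seed": 0, "n_cells": 500, "n_genes": 1523, ...}
{"status": "ok", "command": "train",      "seed": 7, "training_accuracy": 1.0, "final_objective": 0.18691, ...}
```

The preprocessing step kept all 500 cells (every simulated cell detects more
than 1,000 genes) and 1,523 of the 2,000 genes (those whose count exceeds 5
in at least 10% of cells). `report.json` then contains held-out accuracy
mean ± sd per training-subsample rate:

| training data used | 20% | 40% | 60% | 80% | 100% |
|---|---|---|---|---|---|
| accuracy | 0.977 ± 0.015 | 0.993 ± 0.012 | 1.000 | 1.000 | 1.000 |

i.e. with two well-separated simulated groups the classifier is nearly
perfect already from 20% of the training cells and saturates as training
data grows, plus per-class recall/precision (here 1.0/1.0 for both groups).
Everything is reproducible: rerunning with the same `--seed` writes
byte-identical outputs.

The same functionality is available as a library
(`scrmtl.simulate`, `scrmtl.preprocess_pipeline`, `scrmtl.train`,
`scrmtl.predict`, `scrmtl.subsample_curve`, `scrmtl.cv_stability`, ...).

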