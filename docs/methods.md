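# Methods

## Preprocessing

Counts are held cells × genes. The pipeline applies, in order:

1. **Good-cell filter** — keep cells detecting strictly more than
   `min_genes_per_good_cell` genes (non-zero counts; default 1000).
2. **Expressed-gene filter** — evaluated *over the good cells only*: keep
   genes whose count strictly exceeds `min_count_expressed` (default 5) in
   at least `min_fraction_good_cells` (default 10%, inclusive) of the good
   cells. The wording of the rules fixes the boundary semantics: "more
   than" and "exceeds" are strict, "at least" is inclusive, and the gene
   rule refers to good cells, which forces cell filtering first. Good cells
   are not recomputed after gene filtering; a fixed-point iteration would
   be a different (and unmotivated) procedure.
3. **Normalization** — each cell scaled so its library size equals the
   median library size across cells. The step sits behind a `method` enum
   (`library_size` | `none`) so a different transform (e.g. a
   linear-model/normality-based method such as Linnorm) can be plugged in
   without touching the rest of the pipeline; median-library scaling is the
   self-contained default.
4. **Log transform** — `log2(x + 1)`.

Degenerate outcomes (no surviving cells or genes, zero-total cells) raise
explicit errors rather than returning empty matrices.

## The multi-task learner

### Objective

With `T` one-vs-rest tasks over `p` genes, `shared_offset` mode estimates a
shared vector `w0`, per-task offsets `v_t` and unpenalized intercepts `b_t`:

    min  Σ_t L_t(w0 + v_t, b_t) + λ1‖w0‖² + λ2 Σ_t ‖v_t‖²

`l21` mode estimates the full weight matrix `W` under
`λ1‖W‖₂,₁ + λ2‖W‖²_F`, the L2,1 norm grouping each gene (column) across
tasks so that joint feature selection zeroes a gene for every cell type
simultaneously.

`L_t` is the **mean** loss over task `t`'s samples — averaging (rather than
summing) equalizes task influence when class sizes differ, which matters in
one-vs-rest coding where every task sees the same cells but different label
balance. The loss is logistic by default,
`log(1 + exp(−y·(x·w + b)))` evaluated via `logaddexp` for stability;
squared hinge `max(0, 1 − y·(x·w+b))²` is available as the SVM-flavoured
alternative. Both are convex and differentiable, and the logistic choice
keeps decision scores interpretable as log-odds.

Features are standardized (train-set mean/sd; constant features are left
centered) by default because penalized linear models are scale-sensitive;
the scaler is stored in the model and re-applied at prediction.

### Solver

Monotone FISTA with backtracking line search. The smooth part `f` contains
*only* the task losses; every penalty lives in the nonsmooth part `g` and
is handled by an exact proximal step:

* ridge terms: `u ↦ u / (1 + 2·step·λ)` per block;
* L2,1 (+ ridge): ridge shrinkage followed by group soft-thresholding
  `g ↦ g·max(0, 1 − τ/‖g‖₂)` per gene column.

Keeping the quadratic penalties out of `f` makes the backtracked Lipschitz
estimate independent of λ, so the solver converges in tens of iterations
even at λ = 1e8 (where a penalty folded into the gradient would make the
problem hopelessly ill-conditioned). Backtracking doubles the local
Lipschitz estimate until the standard quadratic upper bound holds, and the
estimate is relaxed by ×0.9 per outer iteration so steps can re-grow.
Momentum restarts whenever the candidate would increase the objective, and
the fallback is a plain backtracked proximal step from the current iterate,
which cannot increase the objective — hence the recorded objective trace is
non-increasing by construction, and this is asserted in the tests on every
fit. Iterations stop when the relative objective change drops below `tol`
(default 1e−6) or at `max_iter` (default 1000). Initialization is at zero
and nothing in the solver is random, so identical inputs produce
bit-identical traces; `seed` in the config seeds only downstream procedures
(cross-validation folds).

Degenerate inputs: a task with a single label class warns and proceeds (the
loss remains well defined); NaN/Inf in a design matrix is rejected. Exact
argmax ties at prediction go to the lowest task index, i.e. the
lexicographically first class name.

### Hyperparameters

`λ1`, `λ2` default to 0.01 in the library; protocol-level experiments in
this repository use 0.1/0.1. `cv_select_lambdas` picks a pair from a grid
by per-task stratified k-fold accuracy, breaking ties toward stronger
regularization (larger λ1, then larger λ2) so the choice is deterministic
under duplicated grid values.

## Evaluation protocols

* **Repeated splits** — stratified 80/20 train/test splits. Stratification
  is a deliberate default (plain random splits can lose rare cell types
  entirely); it can be disabled per call. Classes with a single cell go to
  training with a warning. Per-class rounding makes the test-set size match
  the fraction to within one cell per class.
* **Training-size curve** — for each rate in {0.2, …, 1.0} and each run: a
  fresh split, stratified subsampling of the training set to the rate
  (never below one cell per class), fit, test accuracy; reported as mean ±
  sd over runs. The protocol's reference run count is 100; tests and the
  acceptance script run 3–10 for speed, which is a sample-size choice of
  this repository, and the run count is a config field.
* **Per-class metrics** — recall `TP/(TP+FN)` and precision `TP/(TP+FP)`
  per class, with `None` (undefined) rather than a crash when a class is
  never predicted; micro-averaged recall equals overall accuracy.
* **CV stability** — outer stratified k-fold (default 10). Per fold,
  `n_runs` repeated stratified 9:1 inner splits each give a validation
  accuracy (fit on the 90%), plus one test accuracy from a fit on the
  fold's full training part. With 10 folds × 100 runs that is 1,000
  validation accuracies and 10 test accuracies; fold medians summarize
  stability and can be compared between methods with the rank-sum test.
* **Wilcoxon rank-sum** — exact by enumeration of all `C(n, n1)` rank
  assignments when the combined sample is ≤ 12 and tie-free (two-sided
  p = share of assignments at least as extreme in `|W − E[W]|`); otherwise
  a normal approximation with tie-corrected variance and no continuity
  correction. Identical constant samples give p = 1 by convention.

## The count simulator

A simplified Splat-style hierarchical gamma-Poisson generator:

| parameter | default | meaning |
|---|---|---|
| `mean_shape`, `mean_rate` | 0.6, 0.3 | gamma baseline gene means |
| `libsize_location`, `libsize_scale` | 11, 0.2 | log-normal library sizes (≈ 60k counts/cell) |
| `de_prob` | 0.1 | fraction of genes DE per group |
| `de_facLoc`, `de_facScale` | 0.1, 0.4 | log-normal DE factor; inverted with prob 0.5 |
| `dropout_shape` | −1 | logistic slope of dropout vs log mean |
| `dropout_rate_target` | 0.2 | calibrated extra-zero fraction |

Group assignment is multinomial; expected counts are the cell's library
size times the group's normalized mean profile; observed counts are
Poisson. Dropout zeroes entries with probability
`logistic(shape·(log λ − mid))`; `mid` is found by bisection so that the
*expected extra-zero fraction* — P(drop)·P(count would be non-zero),
averaged over entries — equals the target, since a single "dropout rate"
number under-determines the logistic parameters. The realized extra-zero
fraction lands within ±0.05 of the target (typically ±0.005).

Presets `data1`–`data4` fix 2,000 genes, equal group probabilities and
dropout 0.2, with (cells, groups) = (500, 2), (1000, 3), (1500, 4),
(2000, 5). Defaults for everything the presets do not fix follow the
published Splat defaults.

**What the simulator omits** — batch effects, mean–variance (BCV)
inflation beyond Poisson, UMI-specific noise, and trajectory structure.
Simulated groups are therefore cleaner than real cell types: passing the
strong-signal tests shows the estimator and protocols are correct, not
that real-data accuracy will match; the no-DE null tests bracket the other
side (no signal ⇒ majority-baseline accuracy). `de_facLoc = 1.0` is used
as the strong-signal setting in the bracketing checks.

## Problem sizes used in this repository

Tests and the acceptance script run the 500-cell/2,000-gene preset (which
fits in ~1 s per train/test cycle) with 3–10 repeated runs, and the CV
stability protocol at 10 folds × 10 runs; these sizes are the package's
own verification choices and are all configurable upward.

## Known limitations

* No rejection option: every query cell is assigned one of the training
  classes, so novel cell types are silently mapped to the nearest known one.
* Missing query genes are imputed as 0 on the log scale (deterministic and
  sparse-friendly); if the query misses many informative genes, scores
  degrade silently beyond the emitted warning.
* The normal-approximation rank-sum p-value omits the continuity
  correction; for the small fold counts it is applied to, the exact path
  is used anyway.
* Dense in-memory matrices throughout; comfortable to ~10⁴ cells × 10⁴
  genes, not engineered for millions of cells.
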