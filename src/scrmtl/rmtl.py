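"""Regularized multi-task learning: shared-plus-offset and L2,1 modes.

The learner estimates one linear model per binary task.  Two coupling
penalties are supported:

``shared_offset``
    Each task weight decomposes as ``W_t = W0 + V_t`` with a shared
    vector ``W0`` and task-specific offsets ``V_t``.  The objective is

        sum_t  L_t(W0 + V_t, b_t)  +  lambda1 ||W0||^2  +  lambda2 sum_t ||V_t||^2

    where ``L_t`` is the mean logistic or squared-hinge loss of task t.
    ``lambda1`` penalizes the shared component and ``lambda2`` controls
    task relatedness: large ``lambda2`` shrinks all offsets to zero and
    the fit collapses to a single pooled model, while large ``lambda1``
    removes the shared component and the tasks decouple.

``l21``
    The task weights form a matrix ``W`` (tasks x features) penalized by

        sum_t L_t(W_t, b_t) + lambda1 ||W||_{2,1} + lambda2 ||W||_F^2

    where the L2,1 norm sums, over features, the Euclidean norm of each
    feature's weights across tasks — joint feature selection: a feature
    is switched off for all tasks at once.

Both objectives are convex.  They are minimized by monotone FISTA
(accelerated proximal gradient with backtracking line search and
restart-on-increase), so the recorded objective trace is non-increasing
by construction.  The ``shared_offset`` objective is smooth and the
proximal step degenerates to the identity; the ``l21`` mode applies
column-group soft-thresholding each step.

Intercepts are never penalized.  Features are standardized by training
mean and standard deviation by default (penalized linear models are
scale-sensitive); the scaler is stored on the model and re-applied at
prediction time.  Each task's loss is the mean over its samples, which
equalizes task influence under unequal class sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

LOSSES = ("logistic", "squared_hinge")
REGULARIZERS = ("shared_offset", "l21")


@dataclass
class TaskData:
    """One binary task: design matrix, ±1 labels and a name."""

    X: np.ndarray
    y: np.ndarray
    task_name: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError(f"task {self.task_name!r}: X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"task {self.task_name!r}: X has {self.X.shape[0]} rows "
                f"but y has {self.y.shape[0]} entries"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"task {self.task_name!r}: X contains NaN/Inf")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError(f"task {self.task_name!r}: labels must be in {{+1, -1}}")
        if len(np.unique(self.y)) < 2:
            warnings.warn(
                f"task {self.task_name!r} has a single class; the fit is degenerate",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class RMTLConfig:
    loss: str = "logistic"
    regularizer: str = "shared_offset"
    lambda1: float = 0.01
    lambda2: float = 0.01
    max_iter: int = 1000
    tol: float = 1e-6
    step_init: float = 1.0
    seed: int = 0
    standardize: bool = True
    fit_intercept: bool = True

    def __post_init__(self) -> None:
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}, got {self.loss!r}")
        if self.regularizer not in REGULARIZERS:
            raise ValueError(f"regularizer must be one of {REGULARIZERS}, got {self.regularizer!r}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")
        if self.tol <= 0 or self.step_init <= 0 or self.max_iter < 1:
            raise ValueError("tol and step_init must be > 0 and max_iter >= 1")


@dataclass
class RMTLModel:
    """Fitted model: shared vector W0, offsets V, intercepts, scaler, trace.

    The per-task weights are always the derived ``W = W0 + V`` (row t is
    the linear model of task t).  In l21 mode W0 is identically zero and
    V holds the full weight matrix, so the identity still holds.
    """

    W0: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    config: RMTLConfig
    scaler: tuple[np.ndarray, np.ndarray] | None = None
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    task_names: list[str] = field(default_factory=list)

    @property
    def W(self) -> np.ndarray:
        return self.W0[None, :] + self.V

    @property
    def n_tasks(self) -> int:
        return self.V.shape[0]

    @property
    def n_features(self) -> int:
        return self.V.shape[1]


# ---------------------------------------------------------------------------
# losses


def _margin_loss_grad(m: np.ndarray, loss: str) -> tuple[float, np.ndarray]:
    """Mean loss over margins m = y*(Xw+b) and its gradient wrt m."""
    n = m.shape[0]
    if loss == "logistic":
        # log(1+exp(-m)) via logaddexp for stability
        val = float(np.logaddexp(0.0, -m).mean())
        dm = -expit(-m) / n
    elif loss == "squared_hinge":
        h = np.maximum(0.0, 1.0 - m)
        val = float((h * h).mean())
        dm = -2.0 * h / n
    else:  # pragma: no cover
        raise ValueError(f"unknown loss {loss!r}")
    return val, dm


def task_loss(w: np.ndarray, b: float, task: TaskData, loss: str = "logistic") -> float:
    """Mean loss of one task at weights w and intercept b."""
    w = np.asarray(w, dtype=float).ravel()
    if w.shape[0] != task.p:
        raise ValueError(f"weight length {w.shape[0]} does not match {task.p} features")
    m = task.y * (task.X @ w + b)
    val, _ = _margin_loss_grad(m, loss)
    return val


def _task_loss_grad(
    w: np.ndarray, b: float, task: TaskData, loss: str, fit_intercept: bool
) -> tuple[float, np.ndarray, float]:
    m = task.y * (task.X @ w + b)
    val, dm = _margin_loss_grad(m, loss)
    dmy = dm * task.y
    gw = task.X.T @ dmy
    gb = float(dmy.sum()) if fit_intercept else 0.0
    return val, gw, gb


# ---------------------------------------------------------------------------
# objective and prox


def l21_norm(W: np.ndarray) -> float:
    """Sum over features (columns) of the task-wise Euclidean norm."""
    return float(np.linalg.norm(W, axis=0).sum())


def l21_prox(W: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of tau * ||.||_{2,1} with feature (column) groups.

    Each column g maps to g * max(0, 1 - tau/||g||_2), i.e. group
    soft-thresholding: the feature is zeroed across all tasks when its
    joint norm falls below tau.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    W = np.asarray(W, dtype=float)
    if tau == 0:
        return W.copy()
    norms = np.linalg.norm(W, axis=0)
    scale = np.zeros_like(norms)
    nz = norms > tau
    scale[nz] = 1.0 - tau / norms[nz]
    return W * scale[None, :]


def objective(model: RMTLModel, tasks: Sequence[TaskData]) -> float:
    """Full regularized objective of a model on a task list."""
    cfg = model.config
    W = model.W
    total = 0.0
    for t, task in enumerate(tasks):
        total += task_loss(W[t], float(model.intercepts[t]), task, cfg.loss)
    if cfg.regularizer == "shared_offset":
        total += cfg.lambda1 * float(model.W0 @ model.W0)
        total += cfg.lambda2 * float((model.V * model.V).sum())
    else:
        total += cfg.lambda1 * l21_norm(W)
        total += cfg.lambda2 * float((W * W).sum())
    return total


# ---------------------------------------------------------------------------
# solver

def _standardize(tasks: Sequence[TaskData]) -> tuple[list[TaskData], tuple[np.ndarray, np.ndarray]]:
    # one-vs-rest tasks usually share the same X object; avoid stacking copies
    unique: list[np.ndarray] = []
    for task in tasks:
        if not any(task.X is u for u in unique):
            unique.append(task.X)
    stacked = unique[0] if len(unique) == 1 else np.vstack(unique)
    mean = stacked.mean(axis=0)
    scale = stacked.std(axis=0)
    scale[scale == 0] = 1.0  # constant features carry no signal; leave centered at 0
    scaled = {id(u): (u - mean) / scale for u in unique}
    out = []
    for task in tasks:
        Xs = scaled[id(task.X)]
        t = TaskData.__new__(TaskData)  # skip re-validation warnings
        t.X, t.y, t.task_name = Xs, task.y, task.task_name
        out.append(t)
    return out, (mean, scale)


class _Problem:
    """Composite objective F = f + g split for proximal gradient.

    The smooth part f holds only the task losses, so its Lipschitz
    constant is independent of the penalty strengths; every penalty
    (the ridge terms and the L2,1 norm) lives in g and is handled
    exactly by a closed-form prox — ridge shrinkage is
    ``u / (1 + 2*step*lambda)`` and the combined L2,1+ridge prox is
    ridge shrinkage followed by group soft-thresholding.  This keeps
    the solver well conditioned even at extreme lambdas.

    Parameters are packed as a flat vector: shared_offset mode packs
    (W0, V.ravel, b); l21 mode packs (W.ravel, b).
    """

    def __init__(self, tasks: Sequence[TaskData], cfg: RMTLConfig):
        self.tasks = tasks
        self.cfg = cfg
        self.T = len(tasks)
        self.p = tasks[0].p

    # --- packing
    def unpack(self, theta: np.ndarray):
        T, p = self.T, self.p
        if self.cfg.regularizer == "shared_offset":
            W0 = theta[:p]
            V = theta[p : p + T * p].reshape(T, p)
            b = theta[p + T * p :]
            return W0, V, b
        W = theta[: T * p].reshape(T, p)
        b = theta[T * p :]
        return None, W, b

    def init_theta(self) -> np.ndarray:
        T, p = self.T, self.p
        n_par = (p + T * p + T) if self.cfg.regularizer == "shared_offset" else (T * p + T)
        return np.zeros(n_par)

    # --- smooth part: task losses only
    def f_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        cfg = self.cfg
        W0, V, b = self.unpack(theta)
        grad = np.zeros_like(theta)
        T, p = self.T, self.p
        total = 0.0
        if cfg.regularizer == "shared_offset":
            gW0 = np.zeros(p)
            gV = np.zeros((T, p))
            gb = np.zeros(T)
            for t, task in enumerate(self.tasks):
                val, gw, gbt = _task_loss_grad(W0 + V[t], float(b[t]), task, cfg.loss, cfg.fit_intercept)
                total += val
                gW0 += gw
                gV[t] = gw
                gb[t] = gbt
            grad[:p] = gW0
            grad[p : p + T * p] = gV.ravel()
            grad[p + T * p :] = gb
        else:
            W = V
            gW = np.zeros((T, p))
            gb = np.zeros(T)
            for t, task in enumerate(self.tasks):
                val, gw, gbt = _task_loss_grad(W[t], float(b[t]), task, cfg.loss, cfg.fit_intercept)
                total += val
                gW[t] = gw
                gb[t] = gbt
            grad[: T * p] = gW.ravel()
            grad[T * p :] = gb
        return total, grad

    # --- nonsmooth part: every penalty, with an exact prox
    def g(self, theta: np.ndarray) -> float:
        cfg = self.cfg
        W0, V, _ = self.unpack(theta)
        if cfg.regularizer == "shared_offset":
            return cfg.lambda1 * float(W0 @ W0) + cfg.lambda2 * float((V * V).sum())
        W = V
        return cfg.lambda1 * l21_norm(W) + cfg.lambda2 * float((W * W).sum())

    def prox(self, theta: np.ndarray, step: float) -> np.ndarray:
        cfg = self.cfg
        T, p = self.T, self.p
        out = theta.copy()
        if cfg.regularizer == "shared_offset":
            out[:p] = theta[:p] / (1.0 + 2.0 * step * cfg.lambda1)
            out[p : p + T * p] = theta[p : p + T * p] / (1.0 + 2.0 * step * cfg.lambda2)
            return out
        # ridge shrinkage, then group soft-thresholding with a rescaled tau
        alpha = 1.0 + 2.0 * step * cfg.lambda2
        W = theta[: T * p].reshape(T, p) / alpha
        out[: T * p] = l21_prox(W, step * cfg.lambda1 / alpha).ravel()
        return out

    def F(self, theta: np.ndarray) -> float:
        return self.f_grad(theta)[0] + self.g(theta)


def _fista(problem: _Problem, cfg: RMTLConfig) -> tuple[np.ndarray, np.ndarray]:
    """Monotone FISTA with backtracking; returns (theta, objective trace)."""
    x = problem.init_theta()
    y = x.copy()
    t_mom = 1.0
    L = 1.0 / cfg.step_init
    Fx = problem.F(x)
    trace = [Fx]

    def bt_step(point: np.ndarray, L: float) -> tuple[np.ndarray, float, float]:
        """Backtracked prox-gradient step from `point`; returns (z, F(z), L)."""
        fy, gy = problem.f_grad(point)
        while True:
            z = problem.prox(point - gy / L, 1.0 / L)
            dz = z - point
            fz = problem.f_grad(z)[0]
            if fz <= fy + float(gy @ dz) + 0.5 * L * float(dz @ dz) + 1e-12:
                return z, fz + problem.g(z), L
            L *= 2.0
            if L > 1e18:
                return point, fy + problem.g(point), L

    for _ in range(cfg.max_iter):
        z, Fz, L = bt_step(y, L)
        if Fz > Fx:  # restart: momentum overshoot — take plain descent step from x
            t_mom = 1.0
            z, Fz, L = bt_step(x, L)
            if Fz > Fx:  # cannot improve further at any step size
                break
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        y = z + ((t_mom - 1.0) / t_next) * (z - x)
        x, Fprev = z, Fx
        Fx = Fz
        t_mom = t_next
        trace.append(Fx)
        L *= 0.9  # allow the step to grow again
        if abs(Fprev - Fx) <= cfg.tol * max(1.0, abs(Fprev)):
            break
    return x, np.asarray(trace)


def fit(tasks: Sequence[TaskData], config: RMTLConfig | None = None) -> RMTLModel:
    """Fit the multi-task model on a list of binary tasks.

    Deterministic: initialization is at zero and the solver has no
    random component, so identical inputs give bit-identical traces.
    """
    config = config or RMTLConfig()
    if len(tasks) == 0:
        raise ValueError("need at least one task")
    p = tasks[0].p
    for task in tasks:
        if task.p != p:
            raise ValueError(
                f"task {task.task_name!r} has {task.p} features, expected {p}"
            )
    scaler = None
    if config.standardize:
        tasks, scaler = _standardize(tasks)
    problem = _Problem(tasks, config)
    theta, trace = _fista(problem, config)
    W0, V, b = problem.unpack(theta)
    if W0 is None:  # l21 mode: store W in V so W = W0 + V holds
        W0 = np.zeros(p)
    return RMTLModel(
        W0=W0,
        V=V,
        intercepts=b,
        config=config,
        scaler=scaler,
        objective_trace=trace,
        task_names=[t.task_name for t in tasks],
    )


def predict_scores(model: RMTLModel, X: np.ndarray) -> np.ndarray:
    """Per-task linear decision scores X_i . (W0 + V_t) + b_t."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature-count mismatch: model expects {model.n_features} features, "
            f"got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    if model.scaler is not None:
        mean, scale = model.scaler
        X = (X - mean) / scale
    return X @ model.W.T + model.intercepts[None, :]


# ---------------------------------------------------------------------------
# hyperparameter selection


def cv_select_lambdas(
    tasks: Sequence[TaskData],
    config: RMTLConfig,
    lambda1_grid: Sequence[float],
    lambda2_grid: Sequence[float],
    k: int = 5,
) -> tuple[float, float, list[dict]]:
    """Pick (lambda1, lambda2) by per-task stratified k-fold CV accuracy.

    The grid pair maximizing mean held-out binary accuracy across tasks
    and folds wins; ties break toward larger lambda1, then larger
    lambda2 (stronger regularization).
    """
    if len(lambda1_grid) == 0 or len(lambda2_grid) == 0:
        raise ValueError("lambda grids must be non-empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    for task in tasks:
        if task.n < k:
            raise ValueError(f"task {task.task_name!r} has fewer samples than folds")
    folds_per_task = []
    for ti, task in enumerate(tasks):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed + ti)
        folds_per_task.append(list(skf.split(task.X, task.y)))

    table = []
    best = None
    for lam1 in lambda1_grid:
        for lam2 in lambda2_grid:
            cfg = replace(config, lambda1=float(lam1), lambda2=float(lam2))
            accs = []
            for fold in range(k):
                sub_tasks, held = [], []
                for ti, task in enumerate(tasks):
                    tr, te = folds_per_task[ti][fold]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        sub_tasks.append(TaskData(task.X[tr], task.y[tr], task.task_name))
                    held.append((task.X[te], task.y[te]))
                model = fit(sub_tasks, cfg)
                for ti, (Xte, yte) in enumerate(held):
                    s = predict_scores(model, Xte)[:, ti]
                    accs.append(float(np.mean(np.where(s >= 0, 1.0, -1.0) == yte)))
            score = float(np.mean(accs))
            table.append({"lambda1": float(lam1), "lambda2": float(lam2), "cv_accuracy": score})
            key = (score, float(lam1), float(lam2))
            if best is None or key > best[0]:
                best = (key, float(lam1), float(lam2))
    assert best is not None
    return best[1], best[2], table
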