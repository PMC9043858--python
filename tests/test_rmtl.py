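import numpy as np
import pytest
from scipy.optimize import minimize

from scrmtl import (
    RMTLConfig,
    RMTLModel,
    TaskData,
    cv_select_lambdas,
    fit,
    l21_norm,
    l21_prox,
    objective,
    predict_scores,
    task_loss,
)

from conftest import random_tasks

LOG2 = np.log(2.0)


def zero_model(T, p, config) -> RMTLModel:
    return RMTLModel(
        W0=np.zeros(p), V=np.zeros((T, p)), intercepts=np.zeros(T), config=config
    )


class TestTaskLoss:
    def test_zero_weights_logistic_gives_log_two(self):
        rng = np.random.default_rng(0)
        task = TaskData(rng.normal(size=(7, 3)), np.array([1.0, -1, 1, -1, 1, -1, 1]))
        assert task_loss(np.zeros(3), 0.0, task, "logistic") == pytest.approx(LOG2)

    def test_zero_weights_squared_hinge_gives_one(self):
        rng = np.random.default_rng(0)
        task = TaskData(rng.normal(size=(6, 2)), np.array([1.0, -1, 1, -1, 1, -1]))
        assert task_loss(np.zeros(2), 0.0, task, "squared_hinge") == pytest.approx(1.0)

    def test_large_margin_logistic(self):
        # single sample x=(1,0), y=+1 at w=(10,0): log(1+e^-10)
        with pytest.warns(UserWarning, match="single class"):
            task = TaskData(np.array([[1.0, 0.0]]), np.array([1.0]))
        val = task_loss(np.array([10.0, 0.0]), 0.0, task, "logistic")
        assert val == pytest.approx(np.log1p(np.exp(-10.0)), rel=1e-9)

    def test_dimension_mismatch(self):
        task = TaskData(np.zeros((3, 2)), np.array([1.0, -1.0, 1.0]))
        with pytest.raises(ValueError, match="features"):
            task_loss(np.zeros(5), 0.0, task)


class TestObjective:
    @pytest.mark.parametrize("regularizer", ["shared_offset", "l21"])
    def test_zero_parameters_logistic(self, regularizer):
        rng = np.random.default_rng(1)
        tasks = random_tasks(rng, T=3, n=6, p=4)
        cfg = RMTLConfig(lambda1=2.0, lambda2=3.0, regularizer=regularizer)
        assert objective(zero_model(3, 4, cfg), tasks) == pytest.approx(3 * LOG2)

    def test_no_penalty_equals_sum_of_losses(self):
        rng = np.random.default_rng(2)
        tasks = random_tasks(rng, T=2, n=8, p=3)
        cfg = RMTLConfig(lambda1=0.0, lambda2=0.0)
        m = zero_model(2, 3, cfg)
        m.W0 = rng.normal(size=3)
        m.V = rng.normal(size=(2, 3))
        m.intercepts = rng.normal(size=2)
        expected = sum(
            task_loss(m.W0 + m.V[t], m.intercepts[t], tasks[t]) for t in range(2)
        )
        assert objective(m, tasks) == pytest.approx(expected)

    def test_term_by_term_oracle(self):
        # hand-summed loss + lambda1||W0||^2 + lambda2 sum ||V_t||^2
        rng = np.random.default_rng(3)
        tasks = random_tasks(rng, T=2, n=4, p=3)
        cfg = RMTLConfig(lambda1=0.7, lambda2=1.3)
        m = zero_model(2, 3, cfg)
        m.W0 = rng.normal(size=3)
        m.V = rng.normal(size=(2, 3))
        m.intercepts = rng.normal(size=2)
        by_hand = 0.0
        for t, task in enumerate(tasks):
            margins = task.y * (task.X @ (m.W0 + m.V[t]) + m.intercepts[t])
            by_hand += np.mean(np.log1p(np.exp(-margins)))
        by_hand += 0.7 * np.sum(m.W0**2) + 1.3 * np.sum(m.V**2)
        assert objective(m, tasks) == pytest.approx(by_hand, rel=1e-12)

    def test_convexity_midpoint(self):
        rng = np.random.default_rng(4)
        tasks = random_tasks(rng, T=2, n=10, p=3)
        for regularizer in ("shared_offset", "l21"):
            cfg = RMTLConfig(lambda1=0.5, lambda2=0.5, regularizer=regularizer)
            vals = []
            models = []
            for _ in range(2):
                m = zero_model(2, 3, cfg)
                m.W0 = rng.normal(size=3)
                m.V = rng.normal(size=(2, 3))
                m.intercepts = rng.normal(size=2)
                models.append(m)
                vals.append(objective(m, tasks))
            mid = zero_model(2, 3, cfg)
            mid.W0 = (models[0].W0 + models[1].W0) / 2
            mid.V = (models[0].V + models[1].V) / 2
            mid.intercepts = (models[0].intercepts + models[1].intercepts) / 2
            assert objective(mid, tasks) <= np.mean(vals) + 1e-12


class TestL21Prox:
    def test_tau_zero_identity(self):
        rng = np.random.default_rng(5)
        W = rng.normal(size=(3, 4))
        np.testing.assert_array_equal(l21_prox(W, 0.0), W)

    def test_group_annihilated_at_boundary(self):
        W = np.array([[3.0], [4.0]])  # norm 5
        np.testing.assert_allclose(l21_prox(W, 5.0), np.zeros((2, 1)))

    def test_partial_shrinkage(self):
        W = np.array([[3.0], [4.0]])
        np.testing.assert_allclose(l21_prox(W, 2.5), [[1.5], [2.0]])

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            l21_prox(np.ones((2, 2)), -1.0)

    def test_matches_numerical_minimizer(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            g = rng.normal(size=3)
            tau = float(np.abs(rng.normal()))
            ours = l21_prox(g.reshape(-1, 1), tau).ravel()
            res = minimize(
                lambda x: 0.5 * np.sum((x - g) ** 2) + tau * np.linalg.norm(x),
                g,
                method="L-BFGS-B",
                options={"ftol": 1e-16, "gtol": 1e-14},
            )
            np.testing.assert_allclose(ours, res.x, atol=1e-5)

    def test_l21_norm_definition(self):
        W = np.array([[3.0, 0.0], [4.0, 2.0]])
        assert l21_norm(W) == pytest.approx(5.0 + 2.0)


class TestFit:
    def test_huge_lambda2_forces_signal_into_shared(self):
        rng = np.random.default_rng(7)
        tasks = random_tasks(rng, T=1, n=20, p=4)
        m = fit(tasks, RMTLConfig(lambda1=0.01, lambda2=1e8, standardize=False))
        assert np.linalg.norm(m.V[0]) < 1e-3

    def test_separable_toy_reaches_full_training_accuracy(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [-1.0, 0.0], [-2.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        m = fit(
            [TaskData(X, y, "a")],
            RMTLConfig(lambda1=0.0, lambda2=0.0, standardize=False, max_iter=2000),
        )
        scores = predict_scores(m, X)[:, 0]
        assert np.all(np.sign(scores) == y)

    @pytest.mark.parametrize("regularizer", ["shared_offset", "l21"])
    @pytest.mark.parametrize("loss", ["logistic", "squared_hinge"])
    def test_monotone_descent_trace(self, regularizer, loss):
        rng = np.random.default_rng(8)
        tasks = random_tasks(rng, T=2, n=25, p=5)
        cfg = RMTLConfig(
            loss=loss, regularizer=regularizer, lambda1=0.2, lambda2=0.2
        )
        m = fit(tasks, cfg)
        trace = m.objective_trace
        assert np.all(np.diff(trace) <= 1e-10 * np.maximum(1.0, np.abs(trace[:-1])))
        assert np.all(np.isfinite(trace))

    def test_deterministic_refit_bit_identical(self):
        rng = np.random.default_rng(9)
        tasks = random_tasks(rng, T=2, n=15, p=4)
        cfg = RMTLConfig(seed=3)
        m1 = fit(tasks, cfg)
        m2 = fit(tasks, cfg)
        np.testing.assert_array_equal(m1.objective_trace, m2.objective_trace)
        np.testing.assert_array_equal(m1.W, m2.W)

    def test_single_class_task_warns(self):
        X = np.ones((4, 2))
        with pytest.warns(UserWarning, match="single class"):
            TaskData(X, np.ones(4), "mono")

    def test_nan_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            TaskData(X, np.array([1.0, -1, 1, -1]))

    def test_w_identity_holds_in_both_modes(self):
        rng = np.random.default_rng(10)
        tasks = random_tasks(rng, T=2, n=12, p=3)
        for reg in ("shared_offset", "l21"):
            m = fit(tasks, RMTLConfig(regularizer=reg, lambda1=0.1, lambda2=0.1))
            np.testing.assert_array_equal(m.W, m.W0[None, :] + m.V)


class TestPredictScores:
    def test_zero_model_returns_intercepts(self):
        cfg = RMTLConfig(standardize=False)
        m = zero_model(3, 2, cfg)
        m.intercepts = np.array([0.5, -1.0, 2.0])
        scores = predict_scores(m, np.random.default_rng(0).normal(size=(4, 2)))
        np.testing.assert_allclose(scores, np.tile(m.intercepts, (4, 1)))

    def test_matches_explicit_dot_products(self):
        rng = np.random.default_rng(11)
        cfg = RMTLConfig(standardize=False)
        m = zero_model(4, 3, cfg)
        m.W0 = rng.normal(size=3)
        m.V = rng.normal(size=(4, 3))
        m.intercepts = rng.normal(size=4)
        X = rng.normal(size=(3, 3))
        scores = predict_scores(m, X)
        for i in range(3):
            for t in range(4):
                assert scores[i, t] == pytest.approx(
                    X[i] @ (m.W0 + m.V[t]) + m.intercepts[t]
                )

    def test_feature_mismatch_names_counts(self):
        m = zero_model(2, 5, RMTLConfig())
        with pytest.raises(ValueError, match="5"):
            predict_scores(m, np.zeros((3, 4)))


class TestCVSelect:
    def _tasks(self):
        rng = np.random.default_rng(12)
        return random_tasks(rng, T=2, n=40, p=4), rng

    def test_single_grid_point_returned(self):
        tasks, _ = self._tasks()
        lam1, lam2, table = cv_select_lambdas(
            tasks, RMTLConfig(max_iter=100), [0.5], [0.25], k=3
        )
        assert (lam1, lam2) == (0.5, 0.25)
        assert len(table) == 1 and 0 <= table[0]["cv_accuracy"] <= 1

    def test_degrading_lambda_not_selected(self):
        tasks, _ = self._tasks()
        # lambda1=1e6 crushes the shared signal; it must lose to 0.01
        lam1, _, table = cv_select_lambdas(
            tasks, RMTLConfig(max_iter=200), [0.01, 1e6], [0.01], k=3
        )
        accs = {row["lambda1"]: row["cv_accuracy"] for row in table}
        if accs[1e6] < accs[0.01]:
            assert lam1 == 0.01

    def test_duplicate_grid_ties_break_to_larger(self):
        tasks, _ = self._tasks()
        lam1, lam2, _ = cv_select_lambdas(
            tasks, RMTLConfig(max_iter=100), [0.5, 0.5], [0.1, 0.1], k=3
        )
        assert (lam1, lam2) == (0.5, 0.1)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(13)
        tasks = random_tasks(rng, T=1, n=3, p=2)
        with pytest.raises(ValueError, match="fewer samples"):
            cv_select_lambdas(tasks, RMTLConfig(), [0.1], [0.1], k=5)
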