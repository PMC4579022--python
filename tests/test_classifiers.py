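"""GEPSVM, TSVM and the linear-SVM baseline."""

import numpy as np
import pytest
from scipy import linalg, optimize

from dfmorph.classifiers import (fit_gepsvm, fit_linear_svm, fit_tsvm,
                                 predict_gepsvm, predict_linear_svm,
                                 predict_tsvm, svm_primal_objective,
                                 tsvm_primal_objective)

# c1 = c2 chosen at the unit scale of the cross-planes data: the proximal
# term there is O(1e-2), so a small penalty keeps the planes on the lines
CROSS_PLANES_C = 0.01


def train_accuracy(pred1, pred2):
    return (np.sum(pred1 == 1) + np.sum(pred2 == 0)) / (pred1.size + pred2.size)


def best_single_plane_accuracy(X1, X2):
    """Exhaustive grid over single-plane sign classifiers (angle x offset x
    polarity); upper-bounds what any one hyperplane can do on the data."""
    X = np.vstack([X1, X2])
    y = np.concatenate([np.ones(len(X1)), np.zeros(len(X2))])
    best = 0.0
    for ang in np.linspace(0, np.pi, 181):
        w = np.array([np.cos(ang), np.sin(ang)])
        proj = X @ w
        for b in np.quantile(proj, np.linspace(0, 1, 101)):
            pred = (proj - b >= 0).astype(int)
            acc = max(np.mean(pred == y), np.mean((1 - pred) == y))
            best = max(best, acc)
    return best


class TestGEPSVM:
    def test_class_on_plane_gives_zero_eigenvalue_and_recovers_plane(self):
        rng = np.random.default_rng(1)
        w_true, b_true = np.array([1.0, -2.0]), 0.5
        t = rng.uniform(-1, 1, 30)
        X1 = np.c_[t, (t - b_true) / 2.0]        # exactly on w.x - b = 0
        X2 = rng.normal([3, 3], 0.3, (30, 2))
        model = fit_gepsvm(X1, X2, t=0.0)
        assert abs(model.eigenvalues[0]) < 1e-8
        u = np.r_[model.plane1.w, model.plane1.b]
        ref = np.r_[w_true, b_true]
        cosine = abs(u @ ref) / (np.linalg.norm(u) * np.linalg.norm(ref))
        assert cosine == pytest.approx(1.0, abs=1e-6)

    def test_cross_planes_training_accuracy(self, cross_planes):
        X1, X2 = cross_planes
        model = fit_gepsvm(X1, X2, t=1e-4)
        acc = train_accuracy(predict_gepsvm(model, X1), predict_gepsvm(model, X2))
        assert acc == 1.0
        # each returned plane fits its own class better than the other's
        for Xc, plane, other in ((X1, model.plane1, model.plane2),
                                 (X2, model.plane2, model.plane1)):
            own = np.mean((Xc @ plane.w - plane.b) ** 2) / plane.norm**2
            cross = np.mean((Xc @ other.w - other.b) ** 2) / other.norm**2
            assert own < cross

    def test_eigen_residuals_small_on_every_fit(self, cross_planes):
        X1, X2 = cross_planes
        rng = np.random.default_rng(5)
        fits = [fit_gepsvm(X1, X2, t=1e-4),
                fit_gepsvm(rng.normal(0, 1, (25, 4)), rng.normal(1, 1.5, (30, 4)),
                           t=1e-4)]
        for m in fits:
            assert max(m.eigen_residuals) < 1e-6

    def test_minimal_eigenvalue_lower_bounds_random_rayleigh_quotients(self):
        rng = np.random.default_rng(3)
        X1 = rng.normal(0, 1, (25, 4))
        X2 = rng.normal(1, 1.5, (30, 4))
        t = 1e-4
        model = fit_gepsvm(X1, X2, t=t)
        G1 = np.hstack([X1, -np.ones((25, 1))])
        G2 = np.hstack([X2, -np.ones((30, 1))])
        P = G1.T @ G1 + t * np.eye(5)
        Q = G2.T @ G2
        U = rng.standard_normal((100_000, 5))
        rq = np.einsum("ij,jk,ik->i", U, P, U) / np.einsum("ij,jk,ik->i", U, Q, U)
        assert rq.min() >= model.eigenvalues[0] - 1e-9

    def test_prediction_rule_and_tie_break(self):
        # plane1: x = 0; plane2: x = 2
        from dfmorph.classifiers import GEPSVMModel, Plane
        model = GEPSVMModel(plane1=Plane(np.array([1.0, 0.0]), 0.0),
                            plane2=Plane(np.array([1.0, 0.0]), 2.0),
                            tikhonov_t=0.0, eigenvalues=(0, 0),
                            eigen_residuals=(0, 0))
        assert predict_gepsvm(model, np.array([[0.0, 3.0]]))[0] == 1   # on plane1
        assert predict_gepsvm(model, np.array([[2.0, 0.0]]))[0] == 0   # on plane2
        assert predict_gepsvm(model, np.array([[1.0, 0.0]]))[0] == 1   # tie

    def test_scale_invariance_of_predictions(self, cross_planes):
        X1, X2 = cross_planes
        X = np.vstack([X1, X2])
        a = predict_gepsvm(fit_gepsvm(X1, X2, t=1e-4), X)
        b = predict_gepsvm(fit_gepsvm(7.5 * X1, 7.5 * X2, t=1e-4), 7.5 * X)
        np.testing.assert_array_equal(a, b)

    def test_label_swap_symmetry(self, cross_planes):
        X1, X2 = cross_planes
        X = np.vstack([X1, X2])
        a = predict_gepsvm(fit_gepsvm(X1, X2, t=1e-4), X)
        b = predict_gepsvm(fit_gepsvm(X2, X1, t=1e-4), X)
        np.testing.assert_array_equal(a, 1 - b)

    def test_dimension_mismatch_rejected(self, cross_planes):
        X1, X2 = cross_planes
        model = fit_gepsvm(X1, X2, t=1e-4)
        with pytest.raises(ValueError):
            predict_gepsvm(model, np.zeros((1, 5)))

    def test_negative_tikhonov_rejected(self, cross_planes):
        X1, X2 = cross_planes
        with pytest.raises(ValueError):
            fit_gepsvm(X1, X2, t=-1.0)


def tsvm_qp_oracle(X_own, X_other, c):
    """Independent primal QP solve (SLSQP on (w, b, q))."""
    n, p = X_own.shape
    m = X_other.shape[0]
    H = np.hstack([X_own, np.ones((n, 1))])
    G = np.hstack([X_other, np.ones((m, 1))])

    def fun(z):
        u, q = z[:p + 1], z[p + 1:]
        return 0.5 * np.sum((H @ u) ** 2) + c * q.sum()

    cons = [{"type": "ineq", "fun": lambda z: -(G @ z[:p + 1]) + z[p + 1:] - 1.0},
            {"type": "ineq", "fun": lambda z: z[p + 1:]}]
    res = optimize.minimize(fun, np.zeros(p + 1 + m), method="SLSQP",
                            constraints=cons,
                            options={"maxiter": 1000, "ftol": 1e-14})
    assert res.success
    return res.fun


class TestTSVM:
    def test_separated_clusters_classified_perfectly(self):
        rng = np.random.default_rng(7)
        X1 = rng.normal([2, 2], 0.5, (10, 2))
        X2 = rng.normal([-2, -2], 0.5, (10, 2))
        model = fit_tsvm(X1, X2, 1.0, 1.0)
        assert train_accuracy(predict_tsvm(model, X1), predict_tsvm(model, X2)) == 1.0

    def test_objective_matches_independent_qp_oracle(self):
        rng = np.random.default_rng(7)
        X1 = rng.normal([2, 2], 0.5, (10, 2))
        X2 = rng.normal([-2, -2], 0.5, (10, 2))
        model = fit_tsvm(X1, X2, 1.0, 1.0)
        assert model.objectives[0] == pytest.approx(tsvm_qp_oracle(X1, X2, 1.0),
                                                    abs=1e-6)
        assert model.objectives[1] == pytest.approx(tsvm_qp_oracle(X2, X1, 1.0),
                                                    abs=1e-6)

    def test_kkt_residuals_tiny(self, cross_planes):
        X1, X2 = cross_planes
        model = fit_tsvm(X1, X2, CROSS_PLANES_C, CROSS_PLANES_C)
        for kkt in model.kkt_residuals.values():
            assert abs(kkt["duality_gap"]) < 1e-6
            assert kkt["primal_infeasibility"] < 1e-6
            assert kkt["comp_slackness"] < 1e-6

    def test_cross_planes_beats_any_single_plane(self, cross_planes):
        X1, X2 = cross_planes
        model = fit_tsvm(X1, X2, CROSS_PLANES_C, CROSS_PLANES_C)
        acc = train_accuracy(predict_tsvm(model, X1), predict_tsvm(model, X2))
        assert acc == 1.0
        assert best_single_plane_accuracy(X1, X2) <= 0.75

    def test_local_optimality_under_random_perturbations(self):
        rng = np.random.default_rng(8)
        X1 = rng.normal([2, 2], 0.5, (10, 2))
        X2 = rng.normal([-2, -2], 0.5, (10, 2))
        model = fit_tsvm(X1, X2, 1.0, 1.0)
        u_opt = np.r_[model.plane1.w, model.plane1.b]
        obj_opt = model.objectives[0]
        for _ in range(1000):
            u = u_opt + rng.normal(0, 1e-3, 3)
            assert tsvm_primal_objective(X1, X2, u[:2], u[2], 1.0) >= obj_opt - 1e-9

    def test_prediction_symmetry_and_tie_break(self):
        from dfmorph.classifiers import Plane, TSVMModel
        # symmetric planes y = x and y = -x
        model = TSVMModel(plane1=Plane(np.array([1.0, -1.0]), 0.0),
                          plane2=Plane(np.array([1.0, 1.0]), 0.0),
                          c1=1.0, c2=1.0, slack_summaries=(0, 0),
                          objectives=(0, 0))
        assert predict_tsvm(model, np.array([[1.0, 1.0]]))[0] == 1     # on plane1
        # reflection across the bisector (the x-axis) lands on plane2
        assert predict_tsvm(model, np.array([[1.0, -1.0]]))[0] == 0
        assert predict_tsvm(model, np.array([[1.0, 0.0]]))[0] == 1     # tie

    def test_heldout_accuracy_over_draws(self):
        rng = np.random.default_rng(9)
        hits = []
        for _ in range(50):
            X1 = rng.normal([2, 2], 0.5, (15, 2))
            X2 = rng.normal([-2, -2], 0.5, (15, 2))
            model = fit_tsvm(X1[:10], X2[:10], 1.0, 1.0)
            pred1 = predict_tsvm(model, X1[10:])
            pred2 = predict_tsvm(model, X2[10:])
            hits.append(train_accuracy(pred1, pred2))
        assert np.mean(hits) >= 0.95

    def test_label_swap_symmetry(self, cross_planes):
        X1, X2 = cross_planes
        X = np.vstack([X1, X2])
        a = predict_tsvm(fit_tsvm(X1, X2, CROSS_PLANES_C, CROSS_PLANES_C), X)
        b = predict_tsvm(fit_tsvm(X2, X1, CROSS_PLANES_C, CROSS_PLANES_C), X)
        np.testing.assert_array_equal(a, 1 - b)

    def test_invalid_penalties_rejected(self, cross_planes):
        X1, X2 = cross_planes
        with pytest.raises(ValueError):
            fit_tsvm(X1, X2, 0.0, 1.0)


class TestLinearSVM:
    def test_separable_clusters_perfect(self):
        rng = np.random.default_rng(10)
        X1 = rng.normal([3, 3], 0.3, (15, 2))
        X2 = rng.normal([-3, -3], 0.3, (15, 2))
        model = fit_linear_svm(X1, X2, 1.0)
        assert train_accuracy(predict_linear_svm(model, X1),
                              predict_linear_svm(model, X2)) == 1.0

    def test_identical_points_predict_majority(self):
        X1 = np.zeros((3, 2))
        X2 = np.zeros((5, 2))
        model = fit_linear_svm(X1, X2, 1.0)
        assert np.all(predict_linear_svm(model, np.zeros((4, 2))) == 0)

    def test_objective_matches_qp_oracle(self):
        rng = np.random.default_rng(7)
        X1 = rng.normal([2, 2], 0.5, (10, 2))
        X2 = rng.normal([-2, -2], 0.5, (10, 2))
        model = fit_linear_svm(X1, X2, 1.0, tol=1e-12)
        obj = svm_primal_objective(model, X1, X2)
        X = np.vstack([X1, X2])
        y = np.concatenate([np.ones(10), -np.ones(10)])
        p = 2

        def fun(z):
            return 0.5 * z[:p] @ z[:p] + 1.0 * z[p + 1:].sum()

        cons = [{"type": "ineq",
                 "fun": lambda z: y * (X @ z[:p] + z[p]) - 1 + z[p + 1:]},
                {"type": "ineq", "fun": lambda z: z[p + 1:]}]
        res = optimize.minimize(fun, np.zeros(p + 1 + 20), method="SLSQP",
                                constraints=cons,
                                options={"maxiter": 1000, "ftol": 1e-10})
        assert obj == pytest.approx(res.fun, abs=1e-6)

    def test_single_plane_fails_on_cross_planes(self, cross_planes):
        X1, X2 = cross_planes
        model = fit_linear_svm(X1, X2, 1.0)
        acc = train_accuracy(predict_linear_svm(model, X1),
                             predict_linear_svm(model, X2))
        assert acc <= 0.75
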