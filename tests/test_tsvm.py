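"""Twin SVM: dual QP solver, plane recovery, multiclass assembly."""

import numpy as np
import pytest
from scipy import optimize

from wmd.tsvm import (Hyperplane, MulticlassTSVM, predict_binary,
                      predict_multiclass, solve_box_qp, train_binary,
                      train_multiclass)
from wmd.tsvm import _dual_pieces, dual_objective


def oracle_box_qp(M, q, upper):
    """Generic convex-solver oracle: L-BFGS-B on the box-constrained dual."""
    n = len(q)
    res = optimize.minimize(
        lambda a: 0.5 * a @ M @ a - q @ a,
        x0=np.full(n, upper / 2),
        jac=lambda a: M @ a - q,
        bounds=[(0.0, upper)] * n,
        method="L-BFGS-B",
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 20000},
    )
    return res.x


def oracle_train(X_pos, X_neg, c1, c2, eps):
    """Recover both planes from oracle dual solutions."""
    _, SinvGT1, M1 = _dual_pieces(X_pos, X_neg, eps)
    a = oracle_box_qp(M1, np.ones(len(X_neg)), c1)
    u1 = -SinvGT1 @ a
    _, SinvGT2, M2 = _dual_pieces(X_neg, X_pos, eps)
    g = oracle_box_qp(M2, np.ones(len(X_pos)), c2)
    u2 = SinvGT2 @ g
    return (u1, dual_objective(M1, a)), (u2, dual_objective(M2, g))


class TestBoxQpSolver:
    def test_agrees_with_oracle_on_random_instances(self, rng):
        for _ in range(10):
            n = rng.integers(2, 15)
            A = rng.standard_normal((n, n))
            M = A @ A.T + 0.1 * np.eye(n)
            q = rng.standard_normal(n)
            upper = float(rng.uniform(0.5, 5.0))
            a = solve_box_qp(M, q, upper)
            b = oracle_box_qp(M, q, upper)
            f = lambda v: 0.5 * v @ M @ v - q @ v
            assert f(a) == pytest.approx(f(b), abs=1e-8)

    def test_respects_box(self, rng):
        M = np.eye(3)
        a = solve_box_qp(M, np.array([10.0, -10.0, 0.5]), 2.0)
        np.testing.assert_allclose(a, [2.0, 0.0, 0.5])


class TestTrainBinary:
    def test_separable_singletons_classified_correctly(self):
        model = train_binary(np.array([[1.0, 0.0]]), np.array([[-1.0, 0.0]]))
        labels, _ = predict_binary(model, np.array([[1.0, 0.0], [-1.0, 0.0]]))
        np.testing.assert_array_equal(labels, [1, -1])

    def test_toy_planes_match_oracle(self, rng):
        X_pos = np.array([[1, 1], [2, 1], [1.5, 2.0]])
        X_neg = np.array([[-1, -1], [-2, -1], [-1.5, -2.0]])
        model = train_binary(X_pos, X_neg, 1.0, 1.0, 1e-6)
        (u1, obj1), (u2, obj2) = oracle_train(X_pos, X_neg, 1.0, 1.0, 1e-6)
        np.testing.assert_allclose(np.append(model.plane_pos.w, model.plane_pos.b),
                                   u1, atol=1e-4)
        np.testing.assert_allclose(np.append(model.plane_neg.w, model.plane_neg.b),
                                   u2, atol=1e-4)
        assert model.dual_objectives[0] == pytest.approx(obj1, abs=1e-5)
        assert model.dual_objectives[1] == pytest.approx(obj2, abs=1e-5)

    def test_reflection_symmetry(self, rng):
        """Reflecting the data through the origin and swapping classes swaps roles."""
        X_pos = rng.standard_normal((6, 3)) + 2.0
        X_neg = rng.standard_normal((5, 3)) - 2.0
        m = train_binary(X_pos, X_neg)
        m_ref = train_binary(-X_neg, -X_pos)
        pts = rng.standard_normal((20, 3))
        lab, d = predict_binary(m, pts)
        lab_ref, d_ref = predict_binary(m_ref, -pts)
        np.testing.assert_array_equal(lab, -lab_ref)
        np.testing.assert_allclose(d[:, 0], d_ref[:, 1], atol=1e-6)
        np.testing.assert_allclose(d[:, 1], d_ref[:, 0], atol=1e-6)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            train_binary(np.empty((0, 2)), np.array([[1.0, 2.0]]))


class TestPredictBinary:
    def test_point_on_own_plane(self):
        model = train_binary(np.array([[2.0, 0.0], [2.0, 1.0]]),
                             np.array([[-2.0, 0.0], [-2.0, 1.0]]))
        labels, _ = predict_binary(model, np.array([[2.0, 0.5]]))
        assert labels[0] == 1

    def test_distance_invariant_to_plane_rescaling(self):
        h = Hyperplane(np.array([1.0, 2.0]), 0.5)
        h2 = Hyperplane(2 * h.w, 2 * h.b)
        x = np.array([[3.0, -1.0]])
        assert h.distance(x)[0] == pytest.approx(h2.distance(x)[0], rel=1e-12)

    def test_zero_norm_plane_rejected(self):
        with pytest.raises(ValueError):
            Hyperplane(np.zeros(2), 1.0).distance(np.array([[1.0, 1.0]]))


class TestMulticlass:
    @pytest.fixture()
    def clusters(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
        X = np.vstack([c + 0.4 * rng.standard_normal((20, 2)) for c in centers])
        y = np.repeat([f"class{i+1}" for i in range(4)], 20)
        return X, y

    def test_separable_clusters_perfect_training_accuracy(self, clusters):
        X, y = clusters
        model = train_multiclass(X, y)
        y_hat, _ = predict_multiclass(model, X)
        assert np.mean(y_hat == y) == 1.0

    def test_training_is_deterministic(self, clusters):
        X, y = clusters
        a = train_multiclass(X, y)
        b = train_multiclass(X, y)
        for name in a.class_names:
            np.testing.assert_array_equal(a.per_class[name].plane_pos.w,
                                          b.per_class[name].plane_pos.w)

    def test_sample_order_invariance(self, clusters, rng):
        X, y = clusters
        perm = rng.permutation(len(y))
        a = train_multiclass(X, y)
        b = train_multiclass(X[perm], y[perm])
        pts = rng.standard_normal((30, 2)) * 4 + 4
        _, da = predict_multiclass(a, pts)
        _, db = predict_multiclass(b, pts)
        np.testing.assert_allclose(da, db, atol=1e-8)

    def test_missing_class_listed_in_error(self):
        X = np.zeros((4, 2))
        y = ["a", "a", "b", "b"]
        with pytest.raises(ValueError, match="c"):
            train_multiclass(X, y, class_names=["a", "b", "c"])

    def test_dimension_mismatch_rejected(self, clusters):
        X, y = clusters
        model = train_multiclass(X, y)
        with pytest.raises(ValueError, match="dimension"):
            predict_multiclass(model, np.zeros((3, 5)))

    def test_minority_class_beats_nearest_centroid(self, rng):
        """10:1 imbalance: TSVM at least matches a nearest-centroid baseline."""
        maj = rng.standard_normal((200, 2)) + [0.0, 0.0]
        mino = 0.7 * rng.standard_normal((20, 2)) + [2.5, 2.5]
        X = np.vstack([maj, mino])
        y = np.array(["maj"] * 200 + ["min"] * 20)
        model = train_multiclass(X, y)
        test_min = 0.7 * rng.standard_normal((200, 2)) + [2.5, 2.5]
        y_hat, _ = predict_multiclass(model, test_min)
        tsvm_acc = np.mean(y_hat == "min")
        cm = {lab: X[y == lab].mean(axis=0) for lab in ("maj", "min")}
        nc_pred = np.where(
            np.linalg.norm(test_min - cm["min"], axis=1)
            < np.linalg.norm(test_min - cm["maj"], axis=1), "min", "maj")
        assert tsvm_acc >= np.mean(nc_pred == "min")

    def test_json_round_trip(self, clusters):
        X, y = clusters
        model = train_multiclass(X, y)
        clone = MulticlassTSVM.from_json(model.to_json())
        pts = X[:10]
        _, da = predict_multiclass(model, pts)
        _, db = predict_multiclass(clone, pts)
        np.testing.assert_allclose(da, db, rtol=1e-12)
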