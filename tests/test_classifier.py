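"""sMIL training: solver correctness, SVM reduction, calibration, scoring."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVC

from cellkine.classifier import (
    SmilModel,
    classify,
    confidence,
    smil_constraint_set,
    solve_svm_dual,
    svm_objective,
    train_smil,
)


def slsqp_primal_objective(X, y, margins, C):
    """Independent oracle: solve the soft-margin primal with a generic
    NLP solver over (w, b, xi)."""
    n, d = X.shape

    def obj(z):
        w = z[:d]
        xi = z[d + 1 :]
        return 0.5 * w @ w + C * xi.sum()

    def obj_grad(z):
        g = np.zeros_like(z)
        g[:d] = z[:d]
        g[d + 1 :] = C
        return g

    cons = []
    for i in range(n):

        def margin_con(z, i=i):
            w, b, xi = z[:d], z[d], z[d + 1 :]
            return y[i] * (w @ X[i] + b) - margins[i] + xi[i]

        cons.append({"type": "ineq", "fun": margin_con})
    bounds = [(None, None)] * (d + 1) + [(0, None)] * n
    z0 = np.zeros(d + 1 + n)
    z0[d + 1 :] = np.maximum(margins, 1.0)  # feasible start
    res = minimize(
        obj, z0, jac=obj_grad, method="SLSQP", bounds=bounds, constraints=cons,
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    assert res.success, res.message
    return res.fun


class TestSolver:
    def test_hand_solved_two_dimensional_toy(self):
        # negative bag instances (0,0),(0,1); one positive bag {(2,0),(2,1)}
        # of size 2 => margin 0, mean (2, 0.5). Optimum: w=(1/2, 0), b=-1.
        mats = [np.array([[0.0, 0.0], [0.0, 1.0]]), np.array([[2.0, 0.0], [2.0, 1.0]])]
        labels = ["negative", "positive"]
        model = train_smil(mats, labels, C=1.0, tol=1e-10, calibrate=False)
        assert model.weights == pytest.approx([0.5, 0.0], abs=1e-6)
        assert model.bias == pytest.approx(-1.0, abs=1e-6)
        assert model.objective_ == pytest.approx(0.125, abs=1e-6)
        # negatives sit at the -1 margin; the positive bag's instances and
        # mean sit exactly on the boundary (margin (2-2)/2 = 0)
        for x in mats[0]:
            score = float(model.weights @ x + model.bias)
            assert score == pytest.approx(-1.0, abs=1e-6)
            assert classify(score, 0.0) == "negative"
        for x in mats[1]:
            assert float(model.weights @ x + model.bias) == pytest.approx(0.0, abs=1e-6)
        assert model.raw_score(mats[1]) == pytest.approx(0.0, abs=1e-6)

    def test_singleton_bags_reduce_to_standard_svm(self):
        rng = np.random.default_rng(0)
        X_pos = rng.normal(loc=1.5, size=(25, 4))
        X_neg = rng.normal(loc=-1.5, size=(25, 4))
        mats = [row[None, :] for row in X_pos] + [row[None, :] for row in X_neg]
        labels = ["positive"] * 25 + ["negative"] * 25
        model = train_smil(mats, labels, C=1.0, tol=1e-10, calibrate=False)

        X = np.vstack([X_pos, X_neg])
        y = np.array([1] * 25 + [-1] * 25)
        svm = SVC(kernel="linear", C=1.0, tol=1e-8).fit(X, y)

        ours = np.sign(X @ model.weights + model.bias)
        theirs = svm.predict(X)
        assert np.array_equal(ours, theirs)
        # with singleton positives the margin constant (2-1)/1 = 1, so the
        # program is the standard SVM and the parameters agree too
        assert model.weights == pytest.approx(svm.coef_.ravel(), abs=1e-4)
        assert model.bias == pytest.approx(svm.intercept_[0], abs=1e-4)

    @pytest.mark.parametrize("trial", range(20))
    def test_objective_matches_generic_solver(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_bags = rng.integers(2, 10)
        d = rng.integers(2, 5)
        mats, labels = [], []
        for b in range(n_bags):
            size = int(rng.integers(1, 4))
            mats.append(rng.normal(size=(size, d)))
            labels.append("positive" if b % 2 == 0 else "negative")
        C = float(rng.choice([0.5, 1.0, 2.0]))
        X, y, margins, _ = smil_constraint_set(mats, labels)
        w, b, _ = solve_svm_dual(X, y, margins, C, tol=1e-12)
        ours = svm_objective(X, y, margins, C, w, b)
        oracle = slsqp_primal_objective(X, y, margins, C)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_feature_scaling_leaves_predictions_invariant(self):
        # exact inverse scaling of w holds when no slack is active at the
        # optimum (separable data); with active slack the margin/cost
        # tradeoff itself changes under scaling
        rng = np.random.default_rng(5)
        mats = [rng.normal(loc=3, size=(2, 3)), rng.normal(loc=-3, size=(3, 3)),
                rng.normal(loc=3, size=(1, 3)), rng.normal(loc=-3, size=(2, 3))]
        labels = ["positive", "negative", "positive", "negative"]
        m1 = train_smil(mats, labels, C=1.0, tol=1e-10, calibrate=False)
        m2 = train_smil([10.0 * m for m in mats], labels, C=1.0, tol=1e-10, calibrate=False)
        # w scales by the inverse factor, the bias is unchanged
        assert m2.weights == pytest.approx(m1.weights / 10.0, abs=1e-6)
        assert m2.bias == pytest.approx(m1.bias, abs=1e-6)
        test = rng.normal(size=(20, 3))
        s1 = test @ m1.weights + m1.bias
        s2 = (10.0 * test) @ m2.weights + m2.bias
        clear = np.abs(s1) > 1e-8
        assert np.array_equal(np.sign(s1[clear]), np.sign(s2[clear]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_smil([np.ones((1, 2))], ["positive"], C=1.0)

    def test_nonpositive_cost_rejected(self):
        mats = [np.ones((1, 2)), -np.ones((1, 2))]
        with pytest.raises(ValueError):
            train_smil(mats, ["positive", "negative"], C=0.0)


class TestConstraintSet:
    def test_negative_bags_expand_per_instance(self):
        mats = [np.ones((3, 2)), np.zeros((2, 2))]
        X, y, margins, owners = smil_constraint_set(mats, ["negative", "positive"])
        assert X.shape == (4, 2)  # 3 negative instances + 1 positive mean
        assert list(y) == [-1.0, -1.0, -1.0, 1.0]
        assert margins[-1] == pytest.approx((2 - 2) / 2)
        assert margins[:3] == pytest.approx([1.0, 1.0, 1.0])

    @pytest.mark.parametrize("size,expected", [(1, 1.0), (2, 0.0), (4, -0.5), (10, -0.8)])
    def test_positive_bag_margin_schedule(self, size, expected):
        mats = [np.ones((size, 2)), np.zeros((1, 2))]
        _, _, margins, _ = smil_constraint_set(mats, ["positive", "negative"])
        assert margins[0] == pytest.approx(expected)


class TestConfidence:
    def _model(self, a=2.0, c=0.0):
        return SmilModel(weights=np.array([1.0, 0.0]), bias=0.0, C=1.0, calibration=(a, c))

    def test_score_zero_maps_to_half_under_symmetric_calibration(self):
        model = self._model()
        assert confidence(model, np.array([[0.0, 5.0]])) == pytest.approx(0.5)

    def test_monotone_in_raw_score(self):
        model = self._model()
        xs = [np.array([[v, 0.0]]) for v in np.linspace(-3, 3, 13)]
        confs = [confidence(model, x) for x in xs]
        assert all(b > a for a, b in zip(confs, confs[1:]))
        assert all(0.0 < c < 1.0 for c in confs)

    def test_calibrated_separable_data_orders_classes(self):
        rng = np.random.default_rng(11)
        mats = [rng.normal(loc=2, size=(1, 3)) for _ in range(10)] + [
            rng.normal(loc=-2, size=(2, 3)) for _ in range(10)
        ]
        labels = ["positive"] * 10 + ["negative"] * 10
        model = train_smil(mats, labels, C=1.0)
        pos_conf = np.mean([confidence(model, m) for m in mats[:10]])
        neg_conf = np.mean([confidence(model, m) for m in mats[10:]])
        assert pos_conf > neg_conf
        a, _c = model.calibration
        assert a > 0

    @pytest.mark.parametrize(
        "score,threshold,expected",
        [
            (0.93, 0.918, "positive"),
            (0.5, 0.918, "negative"),
            (0.0, 0.0, "positive"),
            (0.2, 0.0, "positive"),
        ],
    )
    def test_threshold_rule(self, score, threshold, expected):
        assert classify(score, threshold) == expected


class TestSerialization:
    def test_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        mats = [rng.normal(loc=1, size=(2, 3)), rng.normal(loc=-1, size=(2, 3))]
        model = train_smil(mats, ["positive", "negative"], C=1.0)
        path = tmp_path / "model.json"
        model.save(path)
        again = SmilModel.load(path)
        assert np.allclose(again.weights, model.weights)
        assert again.bias == pytest.approx(model.bias)
        assert again.calibration == pytest.approx(model.calibration)
        x = rng.normal(size=(3, 3))
        assert confidence(again, x) == pytest.approx(confidence(model, x))
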