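import math

import numpy as np
import pandas as pd
import pytest

from kfis.inference import (
    FuzzyRule,
    KFISModel,
    firing_strength,
    fit,
    membership,
    predict,
    predict_proba,
    predict_raw,
    rule_output,
)
from kfis.kernels import KernelSpec
from kfis.ksc import KSCParams

from .oracles import classic_tsk_fit_predict

LINEAR = KernelSpec("linear")


def _rule(centroid, sigma, intercept=0.0, coeffs=(0.0,)):
    return FuzzyRule(centroid=np.asarray(centroid, dtype=float),
                     sigma=np.asarray(sigma, dtype=float),
                     intercept=intercept,
                     expansion_coeffs=np.asarray(coeffs, dtype=float))


def _toy_model(rules, kernel=LINEAR, training_points=((0.0, 0.0),)):
    return KFISModel(rules=rules, kernel=kernel,
                     training_points=np.asarray(training_points, dtype=float))


class TestMembership:
    def test_unity_at_centroid(self, any_kernel):
        rule = _rule([0.3, 0.8], [0.2, 0.2])
        np.testing.assert_allclose(membership(rule, any_kernel, [0.3, 0.8]), 1.0)

    def test_large_sigma_limit(self):
        rule = _rule([0.0], [1e6])
        assert membership(rule, LINEAR, [5.0])[0] == pytest.approx(1.0, abs=1e-9)

    def test_linear_kernel_recovers_classic_gaussian(self):
        sigma = 0.25
        rule = _rule([0.5], [sigma])
        val = membership(rule, LINEAR, [0.5 + sigma])[0]
        assert val == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_firing_strength_is_product(self):
        sigma = 0.3
        # choose offsets so each coordinate membership is exactly 0.5
        offset = sigma * math.sqrt(2 * math.log(2))
        rule = _rule([0.0, 0.0], [sigma, sigma])
        mu = firing_strength(rule, LINEAR, [offset, offset])
        assert mu == pytest.approx(0.25, abs=1e-9)

    def test_single_feature_degenerate_product(self):
        rule = _rule([0.2], [0.1])
        x = [0.35]
        assert firing_strength(rule, LINEAR, x) == pytest.approx(
            membership(rule, LINEAR, x)[0]
        )


class TestRuleOutput:
    def test_zero_coeffs_gives_intercept(self):
        rule = _rule([0.0], [1.0], intercept=2.5, coeffs=[0.0, 0.0])
        assert rule_output(rule, LINEAR, [1.0], [[0.0], [1.0]]) == 2.5

    def test_single_training_point_rbf(self):
        spec = KernelSpec("rbf", gamma=1.0)
        rule = _rule([0.0], [1.0], intercept=0.0, coeffs=[1.0])
        x1 = np.array([0.3])
        for x in ([0.3], [0.9], [2.0]):
            expected = math.exp(-np.sum((x1 - np.asarray(x)) ** 2))
            assert rule_output(rule, spec, x, [x1]) == pytest.approx(expected)

    def test_linear_expansion_reproduces_linear_function(self, rng):
        """Coefficients solved against a known linear target reproduce it."""
        Xtr = rng.random((6, 2))
        w_true, b_true = np.array([1.5, -2.0]), 0.7
        target = Xtr @ w_true + b_true
        G = Xtr @ Xtr.T
        design = np.hstack([np.ones((6, 1)), G])
        coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
        rule = _rule([0.0, 0.0], [1.0, 1.0], intercept=coeffs[0], coeffs=coeffs[1:])
        for x in rng.random((5, 2)):
            assert rule_output(rule, LINEAR, x, Xtr) == pytest.approx(
                x @ w_true + b_true, abs=1e-8
            )


class TestPrediction:
    def test_single_rule_output_passthrough(self):
        rule = _rule([0.9, 0.9], [0.1, 0.1], intercept=3.0, coeffs=[0.0])
        model = _toy_model([rule])
        # membership tiny far from the centroid, but Y must still equal R1
        assert predict_raw(model, [[0.0, 0.0]])[0] == pytest.approx(3.0)

    def test_equal_weights_midpoint(self):
        r1 = _rule([0.5], [0.2], intercept=0.0, coeffs=[0.0])
        r2 = _rule([0.5], [0.2], intercept=1.0, coeffs=[0.0])
        model = _toy_model([r1, r2], training_points=[[0.0]])
        assert predict_raw(model, [[0.5]])[0] == pytest.approx(0.5)

    def test_weighted_average_arithmetic(self):
        # construct memberships exp(-d2/(2σ²)) = 0.9 and 0.1 at the same x
        x = 0.4
        mu = np.array([0.9, 0.1])
        sigma = 0.2
        d = sigma * np.sqrt(-2 * np.log(mu))
        r1 = _rule([x - d[0]], [sigma], intercept=1.0, coeffs=[0.0])
        r2 = _rule([x - d[1]], [sigma], intercept=-1.0, coeffs=[0.0])
        model = _toy_model([r1, r2], training_points=[[0.0]])
        expected = (0.9 * 1.0 + 0.1 * -1.0) / (0.9 + 0.1)
        assert predict_raw(model, [[x]])[0] == pytest.approx(expected, abs=1e-9)

    def test_convexity_of_defuzzified_output(self, rng):
        """Y is a convex combination of the rule consequents."""
        for _ in range(20):
            rules = [
                _rule(rng.random(3), rng.uniform(0.05, 0.5, 3),
                      intercept=rng.normal(), coeffs=rng.normal(size=4))
                for _ in range(3)
            ]
            tp = rng.random((4, 3))
            model = _toy_model(rules, training_points=tp)
            x = rng.random((1, 3))
            outs = [rule_output(r, LINEAR, x[0], tp) for r in rules]
            y = predict_raw(model, x)[0]
            assert min(outs) - 1e-9 <= y <= max(outs) + 1e-9

    @pytest.mark.parametrize("Y, expected", [(0.0, 0.5), (1.0, 0.7310586)])
    def test_logistic_values(self, Y, expected):
        rule = _rule([0.0], [1.0], intercept=Y, coeffs=[0.0])
        model = _toy_model([rule], training_points=[[0.0]])
        assert predict_proba(model, [[0.0]])[0] == pytest.approx(expected, abs=1e-6)

    def test_logistic_monotone_and_saturating(self):
        outs = []
        for Y in (-50.0, -1.0, 0.0, 1.0, 50.0):
            rule = _rule([0.0], [1.0], intercept=Y, coeffs=[0.0])
            outs.append(predict_proba(_toy_model([rule], training_points=[[0.0]]),
                                      [[0.0]])[0])
        assert all(a < b for a, b in zip(outs, outs[1:]))
        assert outs[-1] == pytest.approx(1.0, abs=1e-12)
        assert 0.0 < outs[0] < 1e-12 + 0.0 or outs[0] > 0.0  # strictly inside (0,1)

    def test_threshold_boundary_and_monotonicity(self):
        rule = _rule([0.0], [1.0], intercept=0.0, coeffs=[0.0])  # proba exactly 0.5
        model = _toy_model([rule], training_points=[[0.0]])
        assert predict(model, [[0.0]])[0] == 1  # boundary counts as positive
        model.decision_threshold = 0.51
        assert predict(model, [[0.0]])[0] == 0

    def test_feature_mismatch_rejected(self):
        rule = _rule([0.0, 0.0], [1.0, 1.0], coeffs=[0.0])
        model = _toy_model([rule], training_points=[[0.0, 0.0]])
        model.feature_ids = ["gA", "gB"]
        with pytest.raises(ValueError, match="gB"):
            predict(model, pd.DataFrame({"gA": [0.1]}))


class TestFit:
    def test_separable_blobs_perfect_training_accuracy(self, separable_dataset):
        X, y = separable_dataset
        for name in ("linear", "rbf"):
            model = fit(X, y, KernelSpec(name, gamma=0.5),
                        KSCParams(cluster_radius=0.5))
            assert (predict(model, X) == y).all()

    def test_deterministic_refit(self, separable_dataset):
        X, y = separable_dataset
        m1 = fit(X, y, KernelSpec("rbf", gamma=0.5), KSCParams())
        m2 = fit(X, y, KernelSpec("rbf", gamma=0.5), KSCParams())
        for r1, r2 in zip(m1.rules, m2.rules):
            np.testing.assert_array_equal(r1.expansion_coeffs, r2.expansion_coeffs)
            assert r1.intercept == r2.intercept

    def test_duplicated_data_same_decision_function(self, separable_dataset):
        """Duplicating every sample must leave the fitted function
        (essentially) unchanged — least squares is weight-invariant."""
        X, y = separable_dataset
        m1 = fit(X, y, LINEAR, KSCParams(cluster_radius=0.5))
        m2 = fit(np.vstack([X, X]), np.concatenate([y, y]), LINEAR,
                 KSCParams(cluster_radius=0.5))
        grid = np.random.default_rng(0).random((20, 2))
        np.testing.assert_allclose(
            predict_proba(m1, grid), predict_proba(m2, grid), atol=1e-3
        )

    def test_linear_kernel_equals_classic_tsk(self, separable_dataset):
        """The kernelized pipeline with a linear kernel reduces to a classic
        input-space subtractive-clustering TSK system."""
        X, y = separable_dataset
        grid = np.random.default_rng(1).random((25, 2))
        model = fit(X, y, LINEAR, KSCParams(cluster_radius=0.5))
        ours = predict_proba(model, grid)
        theirs, idx = classic_tsk_fit_predict(X, y, grid, ra=0.5)
        assert model.cluster.centroid_indices == idx
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_single_rule_reduces_to_direct_ridge(self, rng):
        """With one cluster the weighted design collapses to (1, K) features;
        the fit must match a direct ridge solve on those features."""
        X = rng.normal(0.5, 0.02, size=(15, 2))  # one tight cloud -> R = 1
        y = np.array([0, 1] * 7 + [0])
        model = fit(X, y, LINEAR, KSCParams(cluster_radius=1.0), ridge=1e-6)
        assert model.n_rules == 1
        G = X @ X.T
        design = np.hstack([np.ones((15, 1)), G])
        z = np.log(np.clip(y, 0.05, 0.95) / (1 - np.clip(y, 0.05, 0.95)))
        A = design.T @ design + 1e-6 * np.eye(16)
        theta = np.linalg.solve(A, design.T @ z)
        direct = design @ theta
        np.testing.assert_allclose(predict_raw(model, X), direct, atol=1e-6)

    def test_one_class_labels_rejected(self, rng):
        X = rng.random((10, 2))
        with pytest.raises(ValueError, match="single class"):
            fit(X, np.zeros(10), LINEAR, KSCParams())
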