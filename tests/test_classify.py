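"""Classifiers and LOOCV: hand-computed oracles, degeneracy guards,
tie rules, null calibration."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize

from mieeg.classify import (
    ClassifierSpec,
    ClassificationResult,
    DegenerateVarianceFailure,
    dadf_train_predict,
    knn_predict,
    loocv,
    svm_linear_train_predict,
)
from mieeg.features.registry import FeatureMatrix


def fm_from_array(x: np.ndarray, labels: list[str],
                  name: str = "fft") -> FeatureMatrix:
    return FeatureMatrix(
        values=np.atleast_2d(x), feature_name=name,
        dim_labels=[f"d{i}" for i in range(np.atleast_2d(x).shape[1])],
        conditions=labels)


class TestClassifierSpec:
    @pytest.mark.parametrize("kwargs", [
        {"method": "forest"}, {"method": "knn", "k": 2},
        {"method": "knn", "k": 0}, {"method": "svm_linear", "c": 0.0},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClassifierSpec(**kwargs)


class TestDADF:
    def test_gaussian_posterior_hand_oracle(self):
        # classes at -2 and +2, unit variance: boundary at 0
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-2, 1, 50), rng.normal(2, 1, 50)])
        y = np.array(["rest"] * 50 + ["imagery"] * 50)
        # exact hand-computation with the *empirical* class moments
        def oracle(t):
            best, score = None, -np.inf
            for c in ("imagery", "rest"):
                mu = x[y == c].mean()
                var = x[y == c].var(ddof=1)
                s = (-0.5 * (np.log(2 * np.pi * var) + (t - mu) ** 2 / var)
                     + np.log(0.5))
                if s > score:
                    best, score = c, s
            return best
        for t in (-3.0, -0.5, 0.5, 3.0, 0.1):
            assert dadf_train_predict(x[:, None], y, np.array([t])) == oracle(t)

    def test_zero_within_class_variance_fails(self):
        x = np.array([[1.0, 5.0], [1.0, 6.0], [2.0, 7.0], [3.0, 8.0]])
        y = np.array(["imagery", "imagery", "rest", "rest"])
        with pytest.raises(DegenerateVarianceFailure):
            dadf_train_predict(x, y, np.array([1.5, 6.5]))

    def test_exact_tie_goes_to_larger_prior(self):
        x = np.array([[0.0], [1.0], [0.0], [1.0], [0.0], [1.0]])
        y = np.array(["rest", "rest", "rest", "rest", "imagery", "imagery"])
        # symmetric likelihoods for the midpoint; prior favors rest
        assert dadf_train_predict(x[:4], y[:4], np.array([0.5])) == "rest"

    def test_duplicating_columns_leaves_decision_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 3))
        y = np.array(["imagery", "rest"] * 10)
        t = rng.standard_normal(3)
        assert dadf_train_predict(x, y, t) == dadf_train_predict(
            np.hstack([x, x]), y, np.concatenate([t, t]))


class TestKnn:
    def test_coincident_point_wins_at_k1(self):
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["rest", "imagery", "rest"])
        assert knn_predict(x, y, np.array([1.0]), k=1) == "imagery"

    def test_k3_matches_exhaustive_sorting_oracle(self):
        x = np.array([[0.0], [0.9], [2.0], [3.1], [4.0]])
        y = np.array(["rest", "imagery", "imagery", "rest", "rest"])
        for t in np.linspace(-1, 5, 25):
            order = np.argsort(np.abs(x[:, 0] - t), kind="stable")[:3]
            votes = list(y[order])
            expect = max(set(votes), key=votes.count)
            assert knn_predict(x, y, np.array([t]), k=3) == expect

    def test_distance_ties_break_toward_lower_index(self):
        x = np.array([[1.0], [-1.0], [1.0]])
        y = np.array(["imagery", "rest", "rest"])
        # test point 0: all distances equal; k=1 takes index 0
        assert knn_predict(x, y, np.array([0.0]), k=1) == "imagery"

    def test_k_exceeding_training_size_rejected(self):
        with pytest.raises(ValueError):
            knn_predict(np.zeros((3, 1)), np.array(["a", "b", "a"]),
                        np.zeros(1), k=5)

    def test_duplicating_columns_leaves_decision_unchanged(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((12, 4))
        y = np.array(["imagery", "rest"] * 6)
        t = rng.standard_normal(4)
        for k in (1, 3):
            assert knn_predict(x, y, t, k) == knn_predict(
                np.hstack([x, x]), y, np.concatenate([t, t]), k)


def primal_svm_qp(x: np.ndarray, y: np.ndarray, c: float = 1.0):
    """Reference soft-margin linear SVM via an explicit primal QP."""
    n, d = x.shape
    ys = np.where(y == y[0], 1.0, -1.0)

    def objective(v):
        w, xi = v[:d], v[d + 1:]
        return 0.5 * w @ w + c * xi.sum()

    constraints = [
        {"type": "ineq",
         "fun": (lambda v, i=i:
                 ys[i] * (x[i] @ v[:d] + v[d]) - 1 + v[d + 1 + i])}
        for i in range(n)
    ] + [{"type": "ineq", "fun": lambda v, i=i: v[d + 1 + i]}
         for i in range(n)]
    res = optimize.minimize(
        objective, np.zeros(d + 1 + n), method="SLSQP",
        constraints=constraints,
        options={"maxiter": 500, "ftol": 1e-12})
    assert res.success
    return res.x[:d], res.x[d]


class TestSVM:
    def test_separable_1d_perfect(self):
        x = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = np.array(["rest", "rest", "imagery", "imagery"])
        for t, expect in ((-1.0, "rest"), (1.0, "imagery")):
            assert svm_linear_train_predict(x, y, np.array([t])) == expect

    def test_decision_signs_match_primal_qp_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((10, 2))
        x[:5] += [1.5, 0.5]
        x[5:] -= [1.5, 0.5]
        y = np.array(["imagery"] * 5 + ["rest"] * 5)
        w, b = primal_svm_qp(x, y, c=1.0)
        tests = rng.standard_normal((15, 2)) * 2
        for t in tests:
            margin = t @ w + b
            if abs(margin) < 0.05:
                continue  # skip near-boundary points
            expect = "imagery" if margin > 0 else "rest"
            got = svm_linear_train_predict(x, y, t, standardize=False)
            assert got == expect

    def test_label_inversion_flips_every_prediction(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((12, 3))
        y = np.array(["imagery", "rest"] * 6)
        y_inv = np.array(["rest", "imagery"] * 6)
        flip = {"imagery": "rest", "rest": "imagery"}
        for t in rng.standard_normal((8, 3)):
            a = svm_linear_train_predict(x, y, t)
            b = svm_linear_train_predict(x, y_inv, t)
            assert b == flip[a]

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            svm_linear_train_predict(
                np.zeros((3, 1)), np.array(["a"] * 3), np.zeros(1))


class TestLOOCV:
    def test_label_leaking_feature_gives_perfect_accuracy(self):
        y = ["imagery", "rest"] * 12
        rng = np.random.default_rng(9)
        # label plus a whisper of noise (exactly constant classes would
        # trip the DADF variance guard instead of classifying)
        x = np.array([[1.0] if c == "imagery" else [0.0] for c in y])
        x = x + rng.normal(0, 1e-3, size=x.shape)
        fm = fm_from_array(x, y)
        for spec in (ClassifierSpec(method="dadf"),
                     ClassifierSpec(method="knn", k=1),
                     ClassifierSpec(method="knn", k=3),
                     ClassifierSpec(method="svm_linear")):
            res = loocv(fm, spec)
            assert not res.failed and res.accuracy == 1.0

    def test_majority_vote_overfitting_degeneracy_accuracy_zero(self):
        """Identical rows, balanced classes, k = N-1: every fold's majority
        is the *other* class, so the accuracy is exactly 0."""
        y = ["imagery"] * 24 + ["rest"] * 24
        x = np.ones((48, 3))
        fm = FeatureMatrix(values=x, feature_name="fft",
                           dim_labels=["a", "b", "c"], conditions=y,
                           degenerate_flag=False)
        fm.degenerate_flag = False  # bypass the guard to expose the effect
        res = loocv(fm, ClassifierSpec(method="knn", k=47))
        assert not res.failed
        assert res.accuracy == 0.0

    def test_degenerate_matrix_fails_instead_of_scoring(self):
        y = ["imagery", "rest"] * 12
        fm = fm_from_array(np.ones((24, 2)), y)
        assert fm.degenerate_flag
        res = loocv(fm, ClassifierSpec(method="svm_linear"))
        assert res.failed and "degenerate" in res.reason
        assert np.isnan(res.accuracy)

    def test_dadf_zero_variance_recorded_as_failure(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((24, 3))
        x[:, 1] = 4.2  # constant feature: zero within-class variance
        fm = fm_from_array(x, ["imagery", "rest"] * 12)
        res = loocv(fm, ClassifierSpec(method="dadf"))
        assert res.failed and "variance" in res.reason

    def test_accuracy_invariant_to_trial_permutation(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((20, 4))
        y = ["imagery", "rest"] * 10
        fm = fm_from_array(x, y)
        base = loocv(fm, ClassifierSpec(method="knn", k=3)).accuracy
        perm = rng.permutation(20)
        fm_p = fm_from_array(x[perm], [y[i] for i in perm])
        assert loocv(fm_p, ClassifierSpec(method="knn", k=3)).accuracy == base

    def test_null_features_classify_at_chance_with_svm(self):
        """Uninformative Gaussian features: long-run mean accuracy ~ 0.5."""
        accs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            fm = fm_from_array(rng.standard_normal((48, 6)),
                               ["imagery", "rest"] * 24)
            accs.append(loocv(fm, ClassifierSpec(method="svm_linear")).accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("spec", [
        ClassifierSpec(method="dadf"),
        ClassifierSpec(method="knn", k=1),
        ClassifierSpec(method="knn", k=3),
    ])
    def test_null_calibration_every_method(self, spec):
        accs = []
        for seed in range(150):
            rng = np.random.default_rng(1000 + seed)
            fm = fm_from_array(rng.standard_normal((48, 6)),
                               ["imagery", "rest"] * 24)
            accs.append(loocv(fm, spec).accuracy)
        assert 0.47 <= np.mean(accs) <= 0.53
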