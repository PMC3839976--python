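"""Leave-one-out cross-validated binary classification per subject,
feature and classifier.

Three methods: diagonal-covariance Gaussian discriminant analysis (DADF,
a naive Bayes with class-specific means and variances), k-nearest-neighbor
with Euclidean distance (deterministic tie handling), and a soft-margin
linear SVM.  Method failures (e.g. a zero within-class variance in DADF)
are recorded as failures, never coerced to a chance accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .features.registry import FeatureMatrix


class DegenerateVarianceFailure(RuntimeError):
    """DADF cannot fit: a feature has zero within-class variance."""


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the benchmark classifiers.

    method: 'dadf', 'knn' or 'svm_linear'.  ``k`` (odd, >= 1) applies to
    knn; ``c`` and ``standardize`` to the SVM (z-scoring uses
    training-fold statistics only).
    """

    method: str = "svm_linear"
    k: int = 1
    c: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("dadf", "knn", "svm_linear"):
            raise ValueError(f"unknown method: {self.method!r}")
        if self.method == "knn" and (self.k < 1 or self.k % 2 == 0):
            raise ValueError(f"knn k must be odd and >= 1, got {self.k}")
        if self.c <= 0:
            raise ValueError("svm C must be positive")

    @property
    def name(self) -> str:
        return f"knn_k{self.k}" if self.method == "knn" else self.method


#: The four benchmark classifiers.
DEFAULT_CLASSIFIERS: tuple[ClassifierSpec, ...] = (
    ClassifierSpec(method="dadf"),
    ClassifierSpec(method="knn", k=1),
    ClassifierSpec(method="knn", k=3),
    ClassifierSpec(method="svm_linear"),
)


@dataclass
class ClassificationResult:
    """LOOCV outcome for one subject x feature x classifier.

    Chance statistics (cpro, z, p, iocc) are attached by the evaluation
    stage; ``failed`` results carry a reason and no accuracy.
    """

    feature_name: str
    classifier: str
    subject_id: str = "S00"
    group_tag: str = "responsive"
    predictions: list[str] = field(default_factory=list)
    n_correct: int = 0
    n_total: int = 0
    n1: int = 0
    n2: int = 0
    failed: bool = False
    reason: str = ""
    cpro: float = float("nan")
    z: float = float("nan")
    p: float = float("nan")
    iocc: float = float("nan")

    @property
    def accuracy(self) -> float:
        if self.failed or self.n_total == 0:
            return float("nan")
        return self.n_correct / self.n_total


def dadf_train_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> str:
    """Diagonal-covariance Gaussian discriminant prediction for one row.

    Per class and feature, a Gaussian with the class-specific mean and
    variance; log-densities are summed across features and combined with
    empirical log-priors; the argmax class wins.  Equal posteriors break
    toward the larger-prior class (first class label on an exact tie).
    """
    classes = sorted(set(train_y))
    scores = {}
    priors = {c: np.mean(train_y == c) for c in classes}
    for c in classes:
        rows = train_x[train_y == c]
        mean = rows.mean(axis=0)
        var = rows.var(axis=0, ddof=1)
        # relative floor: a numerically-constant feature (identical values
        # up to rounding) is as degenerate as an exactly-constant one
        floor = (1e-12 * np.maximum(np.abs(mean), 1.0)) ** 2
        degenerate = (var <= floor) | ~np.isfinite(var)
        if degenerate.any():
            raise DegenerateVarianceFailure(
                f"class {c!r}: zero within-class variance in "
                f"{int(degenerate.sum())} feature(s)"
            )
        log_lik = -0.5 * np.sum(
            np.log(2 * np.pi * var) + (test_x - mean) ** 2 / var
        )
        scores[c] = log_lik + np.log(priors[c])
    ordered = sorted(classes, key=lambda c: (-scores[c], -priors[c], c))
    return ordered[0]


def knn_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, k: int
) -> str:
    """Majority label among the k nearest training rows (Euclidean).

    Distance ties break toward the lower training index (stable argsort),
    vote ties toward the class appearing first among the neighbors.
    """
    if k > len(train_y):
        raise ValueError(f"k={k} exceeds training size {len(train_y)}")
    d = np.sqrt(((train_x - test_x) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    votes: dict[str, int] = {}
    for idx in order:
        votes[train_y[idx]] = votes.get(train_y[idx], 0) + 1
    best = max(votes.values())
    for idx in order:  # first-seen class wins a vote tie
        if votes[train_y[idx]] == best:
            return train_y[idx]
    raise AssertionError("unreachable")


def svm_linear_train_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    c: float = 1.0,
    standardize: bool = True,
) -> str:
    """Soft-margin linear SVM prediction for one row.

    Features are z-scored with training-fold statistics when
    ``standardize`` is set; constant features pass through unscaled.
    """
    if len(set(train_y)) < 2:
        raise ValueError("both classes required in the training fold")
    if standardize:
        mu = train_x.mean(axis=0)
        sd = train_x.std(axis=0)
        sd[sd == 0] = 1.0
        train_x = (train_x - mu) / sd
        test_x = (test_x - mu) / sd
    clf = SVC(kernel="linear", C=c)
    clf.fit(train_x, train_y)
    return str(clf.predict(test_x[None, :])[0])


def _predict_one(
    spec: ClassifierSpec,
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
) -> str:
    if spec.method == "dadf":
        return dadf_train_predict(train_x, train_y, test_x)
    if spec.method == "knn":
        return knn_predict(train_x, train_y, test_x, spec.k)
    return svm_linear_train_predict(
        train_x, train_y, test_x, c=spec.c, standardize=spec.standardize
    )


def loocv(features: FeatureMatrix, spec: ClassifierSpec) -> ClassificationResult:
    """Leave-one-out cross-validation of one feature matrix.

    Fold t trains on all rows except t and predicts row t; accuracy is
    the fraction of correct predictions.  Degenerate matrices and
    classifier failures produce a failed result instead of an accuracy.
    """
    y = features.labels_array()
    n1 = int(np.sum(y == "imagery"))
    n2 = int(np.sum(y == "rest"))
    base = dict(
        feature_name=features.feature_name, classifier=spec.name,
        subject_id=features.subject_id, group_tag=features.group_tag,
        n1=n1, n2=n2, n_total=len(y),
    )
    if features.degenerate_flag:
        return ClassificationResult(
            **base, failed=True,
            reason=f"degenerate feature matrix: {features.degenerate_reason}",
        )
    if n1 < 2 or n2 < 2:
        return ClassificationResult(
            **base, failed=True, reason="fewer than 2 trials in a condition",
        )
    x = features.values
    preds: list[str] = []
    mask = np.ones(len(y), dtype=bool)
    try:
        for t in range(len(y)):
            mask[t] = False
            preds.append(_predict_one(spec, x[mask], y[mask], x[t]))
            mask[t] = True
    except DegenerateVarianceFailure as exc:
        return ClassificationResult(**base, failed=True, reason=str(exc))
    n_correct = int(np.sum(np.array(preds) == y))
    return ClassificationResult(**base, predictions=preds, n_correct=n_correct)
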