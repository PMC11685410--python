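"""The five classifier configurations and their normalization contracts.

Everything here is sklearn-compatible: the normalization schemes are
transformers fitted on training rows only, the regulatory feedback network
is a ``BaseEstimator``/``ClassifierMixin`` implementing fit/predict, and
``build_pipeline`` assembles the per-classifier (scaler, estimator) pair
the offline evaluation protocol retrains at every randomization.

Classifier defaults:

* LDA  — linear discriminant, no feature normalization; the SVD solver
  tolerates singular within-class covariance (pseudoinverse behavior).
* KNN  — k = 1, Euclidean, norm-log normalization (sign-preserving log
  compression followed by a [0, 1] unit-range map).
* RFN  — class-mean weight matrix ("mean" training) on unit-range features;
  prediction by multiplicative negative-feedback iteration.
* SVM  — RBF kernel with scale 5.9 (gamma = 1/5.9^2), box constraint 1,
  features mapped to [-1, 1] (0-midrange, 2-range); multiclass by
  one-vs-one voting.
* DT   — Gini splits, at most 100 splits (101 leaves).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "TrainedModel",
    "UnitRangeScaler",
    "MidrangeScaler",
    "NormLogScaler",
    "RegulatoryFeedbackNetwork",
    "build_pipeline",
    "normalize_fit_apply",
    "train",
    "predict",
]

CLASSIFIER_KINDS = ("LDA", "KNN", "RFN", "SVM", "DT")


# ------------------------------------------------------------------ scalers

class MidrangeScaler(TransformerMixin, BaseEstimator):
    """Affine map sending each training column's [min, max] to
    [center - half_range, center + half_range].

    With the defaults (0-midrange, 2-range) this is the [-1, 1] map; test
    values outside the training range extrapolate beyond the interval.
    Zero-range columns map to the constant ``center``.
    """

    def __init__(self, center: float = 0.0, half_range: float = 1.0):
        self.center = center
        self.half_range = half_range

    def fit(self, X, y=None):
        X = validate_data(self, X, reset=True, dtype=float)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        rng = self.data_max_ - self.data_min_
        self.degenerate_ = rng == 0
        safe = np.where(self.degenerate_, 1.0, rng)
        self.scale_ = 2.0 * self.half_range / safe
        self.mid_ = (self.data_max_ + self.data_min_) / 2.0
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        out = (X - self.mid_) * self.scale_ + self.center
        if self.degenerate_.any():
            out[:, self.degenerate_] = self.center
        return out


class UnitRangeScaler(MidrangeScaler):
    """Unitary-range normalization: training column [min, max] -> [0, 1]."""

    def __init__(self):
        super().__init__(center=0.5, half_range=0.5)


class NormLogScaler(TransformerMixin, BaseEstimator):
    """Norm-log normalization: sign-preserving log compression
    ``x -> sign(x) * log(1 + |x|)`` followed by a unit-range map fitted on
    the compressed training columns."""

    def fit(self, X, y=None):
        X = validate_data(self, X, reset=True, dtype=float)
        self._unit = UnitRangeScaler().fit(self._compress(X))
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _compress(X):
        return np.sign(X) * np.log1p(np.abs(X))

    def transform(self, X):
        check_is_fitted(self, "_unit")
        X = validate_data(self, X, reset=False, dtype=float)
        return self._unit.transform(self._compress(X))


# ---------------------------------------------------------------------- RFN

class RegulatoryFeedbackNetwork(ClassifierMixin, BaseEstimator):
    """Regulatory feedback network classifier.

    Training ("mean" type) stores one weight row per class: the mean of that
    class's training feature vectors.  Prediction runs a multiplicative
    negative-feedback iteration: class activities y (uniform start) generate
    an expected input f = W'y, the actual input is compared to the
    expectation (ratio r = x / f), and each activity is rescaled by the
    weight-averaged ratio.  After a fixed number of iterations the class
    with the highest activity wins; exact ties go to the lowest class id.

    Expects nonnegative features (use unit-range normalization upstream);
    negative inputs are clipped at 0.
    """

    def __init__(self, n_iter: int = 25, eps: float = 1e-12):
        self.n_iter = n_iter
        self.eps = eps

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("RFN requires at least 2 classes")
        self.weights_ = np.vstack(
            [X[y == c].mean(axis=0) for c in self.classes_]
        )
        return self

    def _activities(self, X):
        W = np.clip(self.weights_, 0.0, None)
        row_sum = W.sum(axis=1)
        row_sum = np.where(row_sum > 0, row_sum, 1.0)
        X = np.clip(X, 0.0, None)
        n, k = X.shape[0], W.shape[0]
        Y = np.full((n, k), 1.0 / k)
        for _ in range(self.n_iter):
            F = Y @ W                                  # expected input
            R = X / np.maximum(F, self.eps)            # agreement ratio
            Y = Y * (R @ W.T) / row_sum[None, :]
        return Y

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return self._activities(X)

    def predict(self, X):
        A = self.decision_function(X)
        return self.classes_[np.argmax(A, axis=1)]  # argmax -> lowest id on ties


# -------------------------------------------------------------- spec/builder

@dataclass(frozen=True)
class ClassifierSpec:
    """One of the five classifier configurations with its normalization."""

    kind: str
    hyperparams: dict = field(default_factory=dict)
    normalization: str = "default"

    _DEFAULT_NORM = {
        "LDA": "none",
        "KNN": "norm_log",
        "RFN": "unit_range",
        "SVM": "midrange_2range",
        "DT": "none",
    }

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    @property
    def norm_scheme(self) -> str:
        if self.normalization == "default":
            return self._DEFAULT_NORM[self.kind]
        return self.normalization

    def to_json(self) -> dict:
        return {"kind": self.kind, "hyperparams": dict(self.hyperparams),
                "normalization": self.norm_scheme}


def default_specs() -> list[ClassifierSpec]:
    """The paper-configured five, in the conventional order."""
    return [ClassifierSpec(k) for k in CLASSIFIER_KINDS]


def _make_scaler(scheme: str):
    if scheme == "none":
        return None
    if scheme == "unit_range":
        return UnitRangeScaler()
    if scheme == "midrange_2range":
        return MidrangeScaler(center=0.0, half_range=1.0)
    if scheme == "norm_log":
        return NormLogScaler()
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def _make_estimator(spec: ClassifierSpec, seed: int | None):
    hp = dict(spec.hyperparams)
    if spec.kind == "LDA":
        return LinearDiscriminantAnalysis(solver="svd", **hp)
    if spec.kind == "KNN":
        hp.setdefault("n_neighbors", 1)
        return KNeighborsClassifier(metric="euclidean", **hp)
    if spec.kind == "RFN":
        return RegulatoryFeedbackNetwork(**hp)
    if spec.kind == "SVM":
        scale = hp.pop("kernel_scale", 5.9)
        hp.setdefault("C", 1.0)
        return SVC(kernel="rbf", gamma=1.0 / scale**2,
                   decision_function_shape="ovo", **hp)
    if spec.kind == "DT":
        max_splits = hp.pop("max_splits", 100)
        return DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=max_splits + 1,
            random_state=seed, **hp)
    raise ValueError(spec.kind)


def build_pipeline(spec: ClassifierSpec, seed: int | None = None) -> Pipeline:
    """Sklearn pipeline (scaler, classifier) for one configuration."""
    steps = []
    scaler = _make_scaler(spec.norm_scheme)
    if scaler is not None:
        steps.append(("scale", scaler))
    steps.append(("clf", _make_estimator(spec, seed)))
    return Pipeline(steps)


# --------------------------------------------------- functional convenience

def normalize_fit_apply(train_X: np.ndarray, test_X: np.ndarray, scheme: str):
    """Fit a normalization scheme on training rows, apply to both splits.

    Returns (train', test', fitted scaler); ``scheme='none'`` passes data
    through unchanged.
    """
    if train_X.shape[0] == 0:
        raise ValueError("empty training matrix")
    scaler = _make_scaler(scheme)
    if scaler is None:
        return train_X, test_X, None
    tr = scaler.fit_transform(train_X)
    te = scaler.transform(test_X) if test_X.shape[0] else test_X.copy()
    return tr, te, scaler


@dataclass
class TrainedModel:
    """A fitted pipeline plus bookkeeping the evaluation protocol records."""

    spec: ClassifierSpec
    pipeline: Pipeline
    classes: np.ndarray
    columns: list
    train_time_s: float


def train(matrix, spec: ClassifierSpec, seed: int | None = None) -> TrainedModel:
    """Fit one classifier configuration on a FeatureMatrix; wall time is
    recorded with a monotonic clock."""
    y = np.asarray(matrix.labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    pipe = build_pipeline(spec, seed)
    t0 = time.perf_counter()
    pipe.fit(matrix.values, y)
    dt = time.perf_counter() - t0
    return TrainedModel(spec=spec, pipeline=pipe, classes=classes,
                        columns=list(matrix.columns), train_time_s=dt)


def predict(model: TrainedModel, matrix) -> tuple[np.ndarray, float]:
    """Predict labels for a FeatureMatrix; returns (labels, test wall time)."""
    if list(matrix.columns) != model.columns:
        missing = [c for c in model.columns if c not in matrix.columns]
        extra = [c for c in matrix.columns if c not in model.columns]
        raise ValueError(
            f"feature columns do not match training columns; "
            f"missing={missing[:5]}, extra={extra[:5]}"
        )
    if matrix.values.shape[0] == 0:
        return np.array([], dtype=model.classes.dtype), 0.0
    t0 = time.perf_counter()
    labels = model.pipeline.predict(matrix.values)
    dt = time.perf_counter() - t0
    return labels, dt
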