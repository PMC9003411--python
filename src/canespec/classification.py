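"""Irrigation-level classification from spectral features.

Three irrigation amounts (0 / 180 / 300 m3/ha) are treated as classes
and predicted from the five visible-band-dominated features that
correlate most with water input (red and blue reflectance, SRPI, NPCI,
NGBDI).  Models: RBF-kernel C-SVM (one-vs-one multiclass) and a
single-hidden-layer backprop network with softmax output.  Validation
is stratified 3-fold cross-validation; out-of-fold predictions are
pooled into a single confusion matrix so every sample is predicted
exactly once and row totals equal full class sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import resolve_feature_set
from .metrics import ConfusionMatrix
from .regression import _sigmoid, _Standardizer

DEFAULT_FEATURES = ("red", "blue", "SRPI", "NPCI", "NGBDI")
IRRIGATION_LABEL_FMT = "Irrigation_{:g}"


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm + hyperparameters for irrigation classification."""

    algorithm: str  # SVM | BPNN
    C: float = 10.0  # SVM penalty
    gamma: float = 0.167  # RBF kernel coefficient
    multiclass: str = "ovo"  # one-vs-one
    epochs: int = 1000
    learning_rate: float = 0.1
    hidden_units: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("SVM", "BPNN"):
            raise ValueError("algorithm must be SVM or BPNN")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")
        if self.learning_rate <= 0 or self.epochs < 1 or self.hidden_units < 1:
            raise ValueError("invalid BPNN hyperparameters")

    @classmethod
    def svm(cls, C: float = 10.0, gamma: float = 0.167, seed: int = 0) -> "ClassifierSpec":
        return cls("SVM", C=C, gamma=gamma, seed=seed)

    @classmethod
    def bpnn(cls, hidden_units: int = 10, epochs: int = 1000,
             learning_rate: float = 0.1, seed: int = 0) -> "ClassifierSpec":
        return cls("BPNN", hidden_units=hidden_units, epochs=epochs,
                   learning_rate=learning_rate, seed=seed)


def irrigation_feature_correlations(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    irrigation_col: str = "irrigation",
) -> pd.Series:
    """Pearson R of each feature with the (numeric) irrigation amount,
    sorted by |R| descending.  Constant features are reported as NaN
    with a warning rather than dropped silently."""
    from .features import feature_columns

    if irrigation_col not in table.columns:
        raise KeyError(f"no {irrigation_col!r} column in table")
    cols = feature_cols or feature_columns(table)
    w = table[irrigation_col].to_numpy(float)
    out = {}
    for c in cols:
        x = table[c].to_numpy(float)
        if np.std(x) == 0:
            warnings.warn(f"feature {c!r} is constant: R undefined", stacklevel=2)
            out[c] = np.nan
        else:
            out[c] = float(np.corrcoef(x, w)[0, 1])
    s = pd.Series(out, name="R_with_irrigation")
    return s.reindex(s.abs().sort_values(ascending=False).index)


def kfold_split(
    table: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    stratify_col: str = "irrigation",
) -> list[np.ndarray]:
    """Stratified k-fold partition of row positions; per-class fold
    sizes within one of each other; deterministic by seed."""
    y = table[stratify_col].to_numpy()
    _, counts = np.unique(y, return_counts=True)
    if np.any(counts < k):
        raise ValueError(f"every class needs >= k={k} members, got counts {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


class FittedClassifier:
    def __init__(self, spec, feature_cols, classes, x_scaler, predict_std):
        self.spec = spec
        self.feature_cols = list(feature_cols)
        self.classes = classes
        self._x_scaler = x_scaler
        self._predict_std = predict_std

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = self._x_scaler(table[self.feature_cols].to_numpy(float))
        return self._predict_std(X)


def fit_classifier(
    spec: ClassifierSpec,
    training: pd.DataFrame,
    feature_cols: list[str],
    label_col: str = "irrigation",
) -> FittedClassifier:
    """Train one classifier; inputs z-scored on training-fold statistics.

    SVM: C-support-vector classification, RBF kernel with the given
    gamma, one-vs-one multiclass (ties broken deterministically by
    decision value, then class order).  BPNN: sigmoid hidden layer,
    softmax output trained by full-batch cross-entropy gradient
    descent, seeded uniform [-0.5, 0.5] initialisation.
    """
    X = training[feature_cols].to_numpy(float)
    y = training[label_col].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contain a single class")
    scaler = _Standardizer(X)
    Xs = scaler(X)

    if spec.algorithm == "SVM":
        svc = SVC(
            C=spec.C,
            kernel="rbf",
            gamma=spec.gamma,
            decision_function_shape=spec.multiclass,
            random_state=spec.seed,
        )
        svc.fit(Xs, y)
        predict_std = svc.predict
    else:
        rng = np.random.default_rng(spec.seed)
        d, h, kcls = Xs.shape[1], spec.hidden_units, len(classes)
        W1 = rng.uniform(-0.5, 0.5, size=(d, h))
        b1 = rng.uniform(-0.5, 0.5, size=h)
        W2 = rng.uniform(-0.5, 0.5, size=(h, kcls))
        b2 = rng.uniform(-0.5, 0.5, size=kcls)
        Y = (y[:, None] == classes[None, :]).astype(float)  # one-hot
        n = len(Xs)
        lr = spec.learning_rate
        for _ in range(spec.epochs):
            H = _sigmoid(Xs @ W1 + b1)
            logits = H @ W2 + b2
            logits -= logits.max(axis=1, keepdims=True)
            P = np.exp(logits)
            P /= P.sum(axis=1, keepdims=True)
            err = (P - Y) / n  # softmax cross-entropy gradient
            gW2 = H.T @ err
            gb2 = err.sum(axis=0)
            dH = (err @ W2.T) * H * (1.0 - H)
            gW1 = Xs.T @ dH
            gb1 = dH.sum(axis=0)
            W2 -= lr * gW2
            b2 -= lr * gb2
            W1 -= lr * gW1
            b1 -= lr * gb1

        def predict_std(Z, W1=W1, b1=b1, W2=W2, b2=b2, classes=classes):
            H = _sigmoid(Z @ W1 + b1)
            # argmax breaks ties by class order -> deterministic
            return classes[np.argmax(H @ W2 + b2, axis=1)]

    return FittedClassifier(spec, feature_cols, classes, scaler, predict_std)


def cross_validated_confusion(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    features: list[str] = list(DEFAULT_FEATURES),
    k: int = 3,
    seed: int = 0,
    label_col: str = "irrigation",
) -> ConfusionMatrix:
    """Pooled k-fold confusion matrix: each sample is predicted once,
    when its fold is held out, and counts are summed over folds."""
    cols = resolve_feature_set(table, features)
    folds = kfold_split(table, k=k, seed=seed, stratify_col=label_col)
    levels = np.sort(pd.unique(table[label_col]))
    labels = tuple(IRRIGATION_LABEL_FMT.format(lv) for lv in levels)
    index = {lv: i for i, lv in enumerate(levels)}
    counts = np.zeros((len(levels), len(levels)), dtype=np.int64)
    all_pos = np.arange(len(table))
    for test in folds:
        train = np.setdiff1d(all_pos, test)
        model = fit_classifier(spec, table.iloc[train], cols, label_col)
        pred = model.predict(table.iloc[test])
        actual = table.iloc[test][label_col].to_numpy()
        for a, p in zip(actual, pred):
            counts[index[a], index[p]] += 1
    return ConfusionMatrix(labels, counts)
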