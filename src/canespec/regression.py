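"""Canopy-nitrogen regression: PLS, backprop neural net, and extreme
learning machine on configurable spectral feature sets.

The experiment design is a single 7:3 hold-out split of the grid-level
samples into calibration and validation sets; each (feature set x
algorithm) pair is fitted on the same split and scored with Pearson R
and RMSE on both sets.

Inputs are z-scored using calibration-set statistics only (sigmoid
hidden layers saturate on raw reflectance scales and PLS is scale
sensitive); the target is centred/scaled the same way internally and
predictions are returned on the original % scale.  Validation data
never touch the fitted statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .features import resolve_feature_set
from .metrics import pearson_r, rmse


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out split: calibration fraction, seed, optional stratification
    on a grouping column (e.g. plot_id)."""

    calibration_fraction: float = 0.7
    seed: int = 0
    stratify_by: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration_fraction must lie in (0, 1)")


def split_holdout(table: pd.DataFrame, spec: SplitSpec = SplitSpec()):
    """Split rows into (calibration, validation), round-to-nearest on
    the calibration size, deterministic for a given seed."""
    n = len(table)
    if n < 10:
        raise ValueError(f"need >= 10 samples to split, got {n}")
    n_cal = int(np.floor(spec.calibration_fraction * n + 0.5))
    if n_cal == 0 or n_cal == n:
        raise ValueError("calibration fraction yields an empty partition")
    rng = np.random.default_rng(spec.seed)

    if spec.stratify_by is None:
        idx = rng.permutation(n)
        cal_pos = np.sort(idx[:n_cal])
        val_pos = np.sort(idx[n_cal:])
    else:
        groups = table[spec.stratify_by].to_numpy()
        # proportional allocation per stratum, largest remainder to hit
        # n_cal exactly
        cal_positions: list[np.ndarray] = []
        strata = pd.unique(groups)
        quotas, remainders, members = [], [], []
        for g in strata:
            pos = np.flatnonzero(groups == g)
            share = spec.calibration_fraction * len(pos)
            quotas.append(int(np.floor(share)))
            remainders.append(share - np.floor(share))
            members.append(pos)
        deficit = n_cal - sum(quotas)
        for i in np.argsort(remainders)[::-1][:max(deficit, 0)]:
            quotas[i] += 1
        for pos, q in zip(members, quotas):
            take = rng.permutation(len(pos))[:q]
            cal_positions.append(pos[take])
        cal_pos = np.sort(np.concatenate(cal_positions)) if cal_positions else np.array([], int)
        val_pos = np.setdiff1d(np.arange(n), cal_pos)
    return table.iloc[cal_pos].copy(), table.iloc[val_pos].copy()


@dataclass(frozen=True)
class RegressorSpec:
    """Algorithm + hyperparameters for one CNC regression model."""

    algorithm: str  # PLS | BPNN | ELM
    n_components: int = 6  # PLS latent components
    epochs: int = 1000  # BPNN full-batch iterations
    learning_rate: float = 0.05
    hidden_units: int = 22  # BPNN; ELM default overridden below
    activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("PLS", "BPNN", "ELM"):
            raise ValueError("algorithm must be PLS, BPNN or ELM")
        if self.n_components < 1 or self.hidden_units < 1 or self.epochs < 1:
            raise ValueError("sizes and epochs must be positive integers")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    @classmethod
    def pls(cls, n_components: int = 6, seed: int = 0) -> "RegressorSpec":
        return cls("PLS", n_components=n_components, seed=seed)

    @classmethod
    def bpnn(cls, hidden_units: int = 22, epochs: int = 1000,
             learning_rate: float = 0.05, seed: int = 0) -> "RegressorSpec":
        return cls("BPNN", hidden_units=hidden_units, epochs=epochs,
                   learning_rate=learning_rate, seed=seed)

    @classmethod
    def elm(cls, hidden_units: int = 50, seed: int = 0) -> "RegressorSpec":
        return cls("ELM", hidden_units=hidden_units, seed=seed)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Standardizer:
    """z-score transform frozen on calibration statistics."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        self.sd = X.std(axis=0, ddof=0)
        if np.any(self.sd == 0):
            bad = np.flatnonzero(self.sd == 0)
            raise ValueError(f"constant feature column(s) at positions {bad.tolist()}")

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


class FittedRegressor:
    """A trained CNC model bound to its feature columns and scalers."""

    def __init__(self, spec, feature_cols, target_col, x_scaler, y_mean, y_scale, predict_std):
        self.spec = spec
        self.feature_cols = list(feature_cols)
        self.target_col = target_col
        self._x_scaler = x_scaler
        self._y_mean = y_mean
        self._y_scale = y_scale
        self._predict_std = predict_std  # maps standardized X -> standardized y

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_cols].to_numpy(float)
        z = self._predict_std(self._x_scaler(X))
        return self._y_mean + self._y_scale * np.ravel(z)


def fit_regressor(
    spec: RegressorSpec,
    calibration: pd.DataFrame,
    feature_cols: list[str],
    target_col: str = "cnc",
) -> FittedRegressor:
    """Train one regressor on the calibration table.

    PLS: NIPALS partial least squares with `n_components` latent
    variables.  BPNN: one sigmoid hidden layer, linear output,
    full-batch gradient descent, weights initialised uniform in
    [-0.5, 0.5] from the spec seed.  ELM: random (seeded) input weights
    and biases, sigmoid hidden layer, output weights by least-squares
    pseudoinverse.
    """
    X = calibration[feature_cols].to_numpy(float)
    y = calibration[target_col].to_numpy(float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("calibration table contains missing values")
    scaler = _Standardizer(X)
    Xs = scaler(X)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=0))
    y_scale = y_sd if y_sd > 0 else 1.0
    ys = (y - y_mean) / y_scale

    if spec.algorithm == "PLS":
        if spec.n_components > len(feature_cols):
            raise ValueError(
                f"n_components={spec.n_components} exceeds n_features={len(feature_cols)}"
            )
        rank = np.linalg.matrix_rank(Xs)
        if rank < spec.n_components:
            raise ValueError(
                f"design matrix rank {rank} < n_components={spec.n_components}"
            )
        pls = PLSRegression(n_components=spec.n_components, scale=False)
        pls.fit(Xs, ys)
        predict_std = lambda Z: pls.predict(Z)  # noqa: E731
    elif spec.algorithm == "ELM":
        rng = np.random.default_rng(spec.seed)
        W = rng.uniform(-1.0, 1.0, size=(Xs.shape[1], spec.hidden_units))
        b = rng.uniform(-1.0, 1.0, size=spec.hidden_units)
        H = _sigmoid(Xs @ W + b)
        Ha = np.hstack([H, np.ones((len(H), 1))])
        beta, *_ = np.linalg.lstsq(Ha, ys, rcond=None)

        def predict_std(Z, W=W, b=b, beta=beta):
            Hz = _sigmoid(Z @ W + b)
            return np.hstack([Hz, np.ones((len(Hz), 1))]) @ beta
    else:  # BPNN
        rng = np.random.default_rng(spec.seed)
        d, h = Xs.shape[1], spec.hidden_units
        W1 = rng.uniform(-0.5, 0.5, size=(d, h))
        b1 = rng.uniform(-0.5, 0.5, size=h)
        w2 = rng.uniform(-0.5, 0.5, size=(h, 1))
        b2 = rng.uniform(-0.5, 0.5, size=1)
        Y = ys[:, None]
        n = len(Xs)
        lr = spec.learning_rate
        for _ in range(spec.epochs):
            H = _sigmoid(Xs @ W1 + b1)
            pred = H @ w2 + b2
            err = pred - Y  # d(MSE/2)/d pred, up to 1/n
            gw2 = H.T @ err / n
            gb2 = err.mean(axis=0)
            dH = (err @ w2.T) * H * (1.0 - H)
            gW1 = Xs.T @ dH / n
            gb1 = dH.mean(axis=0)
            w2 -= lr * gw2
            b2 -= lr * gb2
            W1 -= lr * gW1
            b1 -= lr * gb1

        def predict_std(Z, W1=W1, b1=b1, w2=w2, b2=b2):
            return _sigmoid(Z @ W1 + b1) @ w2 + b2

    return FittedRegressor(spec, feature_cols, target_col, scaler, y_mean, y_scale, predict_std)


def evaluate_regressor(model: FittedRegressor, table: pd.DataFrame):
    """(Pearson R, RMSE) of the model on a labelled table.

    R is None (with a warning) when predictions are constant; RMSE is
    always returned.
    """
    y = table[model.target_col].to_numpy(float)
    yhat = model.predict(table)
    return pearson_r(y, yhat), rmse(y, yhat)


@dataclass(frozen=True)
class FitReport:
    """Calibration/validation accuracy of one (feature set, algorithm)."""

    algorithm: str
    feature_set: str
    r_c: float | None
    rmse_c: float
    r_v: float | None
    rmse_v: float
    n_c: int
    n_v: int


def run_cnc_experiment(
    table: pd.DataFrame,
    feature_sets: dict[str, list[str]],
    specs: list[RegressorSpec],
    split: SplitSpec = SplitSpec(),
    target_col: str = "cnc",
) -> list[FitReport]:
    """Fit every (feature set x algorithm) pair on one shared hold-out
    split and report calibration/validation R and RMSE, sorted by
    validation R descending.

    PLS components are capped at the feature-set size, so the default
    6-component spec runs unchanged on the 5-band-only set.
    """
    if not feature_sets:
        raise ValueError("feature_sets must not be empty")
    resolved = {}
    for name, feats in feature_sets.items():
        if not feats:
            raise ValueError(f"feature set {name!r} is empty")
        resolved[name] = resolve_feature_set(table, feats)
    cal, val = split_holdout(table, split)
    reports = []
    from dataclasses import replace

    for fs_name, cols in resolved.items():
        for spec in specs:
            if spec.algorithm == "PLS" and spec.n_components > len(cols):
                spec = replace(spec, n_components=len(cols))
            model = fit_regressor(spec, cal, cols, target_col)
            r_c, rm_c = evaluate_regressor(model, cal)
            r_v, rm_v = evaluate_regressor(model, val)
            reports.append(
                FitReport(spec.algorithm, fs_name, r_c, rm_c, r_v, rm_v, len(cal), len(val))
            )
    reports.sort(key=lambda r: (-(r.r_v if r.r_v is not None else -np.inf), r.rmse_v))
    return reports


def reports_to_frame(reports: list[FitReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
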