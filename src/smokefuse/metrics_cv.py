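"""Evaluation metrics and the k-fold cross-validation harness.

The four headline metrics of air-quality model evaluation are implemented
on paired prediction/observation vectors:

* MAE   — mean absolute error, same units as the field.
* RMSE  — root mean squared error.
* FB    — fractional bias in percent, ``200 * (P̄ - Ō) / (P̄ + Ō)`` by the
  means-based convention common in air-quality evaluation (a paired-mean
  variant is available); negative FB means under-prediction.
* R²    — squared Pearson correlation by default (the usual convention for
  out-of-sample satellite-AOD/PM2.5 fusion skill); the coefficient of
  determination ``1 - SS_res/SS_tot`` is available behind a flag.

`cross_validate` runs the standard k-fold protocol (default k = 10): samples
are randomly partitioned into k near-equal folds, each fold is predicted by
a model trained on the other k-1, and metrics are computed on the pooled
out-of-fold predictions (per-fold mean ± sd is reported alongside, since
the two summaries can differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .errors import DegenerateFoldError, UndefinedMetricError, ValidationError

__all__ = [
    "EvalReport",
    "FoldAssignment",
    "mae",
    "rmse",
    "fractional_bias",
    "r_squared",
    "pearson_r",
    "kfold_split",
    "make_learner",
    "cross_validate",
    "CvOutcome",
    "METHODS",
    "DEFAULT_HYPER",
]

METHODS = ("mlr", "gbm", "rf")

#: Default hyperparameters for the three fusion learners.  MLR has none;
#: GBM uses many shallow trees with early stopping on an internal 20%
#: validation slice; RF uses 500 fully grown trees with sqrt-feature
#: subsetting at each split.
DEFAULT_HYPER: dict[str, dict] = {
    "mlr": {},
    "gbm": {
        "n_estimators": 1000,
        "max_depth": 3,
        "learning_rate": 0.05,
        "validation_fraction": 0.2,
        "n_iter_no_change": 10,
    },
    "rf": {
        "n_estimators": 500,
        "max_features": "sqrt",
        "n_jobs": 1,
    },
}


def _paired(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64).ravel()
    obs = np.asarray(obs, dtype=np.float64).ravel()
    if pred.shape != obs.shape:
        raise ValidationError(
            f"pred and obs lengths differ: {pred.size} vs {obs.size}"
        )
    if pred.size == 0:
        raise ValidationError("empty prediction/observation vectors")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ValidationError("pred/obs must be finite")
    return pred, obs


def mae(pred, obs) -> float:
    pred, obs = _paired(pred, obs)
    return float(np.mean(np.abs(pred - obs)))


def rmse(pred, obs) -> float:
    pred, obs = _paired(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def fractional_bias(pred, obs, variant: str = "means") -> float:
    """Fractional bias in percent; negative values mean under-prediction."""
    pred, obs = _paired(pred, obs)
    if variant == "means":
        denom = pred.mean() + obs.mean()
        if denom == 0:
            raise UndefinedMetricError("fractional bias undefined: mean(pred) + mean(obs) = 0")
        return float(100.0 * 2.0 * (pred.mean() - obs.mean()) / denom)
    if variant == "paired":
        denom = pred + obs
        if np.any(denom == 0):
            raise UndefinedMetricError("paired fractional bias undefined: some pred + obs = 0")
        return float(100.0 * np.mean(2.0 * (pred - obs) / denom))
    raise ValidationError(f"unknown FB variant {variant!r}")


def pearson_r(pred, obs) -> float:
    pred, obs = _paired(pred, obs)
    if pred.size < 2:
        raise UndefinedMetricError("correlation needs at least 2 samples")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise UndefinedMetricError("correlation undefined for constant input")
    return float(stats.pearsonr(pred, obs).statistic)


def r_squared(pred, obs, variant: str = "pearson") -> float:
    pred, obs = _paired(pred, obs)
    if pred.size < 2:
        raise UndefinedMetricError("R^2 needs at least 2 samples")
    if np.ptp(obs) == 0:
        raise UndefinedMetricError("R^2 undefined for constant observations")
    if variant == "pearson":
        return pearson_r(pred, obs) ** 2
    if variant == "ss":
        ss_res = float(np.sum((obs - pred) ** 2))
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValidationError(f"unknown R^2 variant {variant!r}")


@dataclass
class EvalReport:
    """Summary metrics for one prediction/observation pairing."""

    mae: float
    fb: float
    r2: float
    rmse: float
    n: int
    pearson_r: float | None = None

    @classmethod
    def from_predictions(cls, pred, obs) -> "EvalReport":
        pred, obs = _paired(pred, obs)
        return cls(
            mae=mae(pred, obs),
            fb=fractional_bias(pred, obs),
            r2=r_squared(pred, obs),
            rmse=rmse(pred, obs),
            n=int(pred.size),
            pearson_r=pearson_r(pred, obs),
        )

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "fb": self.fb,
            "r2": self.r2,
            "rmse": self.rmse,
            "n": self.n,
            "pearson_r": self.pearson_r,
        }


@dataclass
class FoldAssignment:
    """A random partition of ``n`` samples into ``k`` near-equal folds."""

    k: int
    fold_of: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of, dtype=np.int64)
        sizes = np.bincount(self.fold_of, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValidationError("fold sizes must differ by at most 1")

    @property
    def n(self) -> int:
        return self.fold_of.size


def kfold_split(n: int, k: int = 10, seed: int = 0) -> FoldAssignment:
    if k < 2:
        raise ValidationError(f"need k >= 2 folds, got {k}")
    if n < k:
        raise ValidationError(f"cannot split n={n} samples into k={k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    # round-robin over the permutation: sizes differ by at most 1
    fold_of[perm] = np.arange(n) % k
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


def make_learner(method: str, hyper: dict | None = None, seed: int = 0):
    """Construct an unfitted regressor for 'mlr', 'gbm' or 'rf'."""
    method = method.lower()
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")
    params = dict(DEFAULT_HYPER[method])
    params.update(hyper or {})
    if method == "mlr":
        return LinearRegression(**params)
    if method == "gbm":
        return GradientBoostingRegressor(random_state=seed, **params)
    return RandomForestRegressor(random_state=seed, **params)


@dataclass
class CvOutcome:
    oof_pred: np.ndarray
    report: EvalReport
    per_fold: pd.DataFrame
    fold_mean: dict = field(default_factory=dict)
    fold_std: dict = field(default_factory=dict)


def cross_validate(
    features,
    target,
    learner_spec: str,
    folds: FoldAssignment,
    hyper: dict | None = None,
    seed: int = 0,
) -> CvOutcome:
    """k-fold cross-validation of one learner.

    Every sample is predicted exactly once, by a model never trained on it.
    The primary report is computed on the pooled out-of-fold predictions;
    per-fold metrics with mean ± sd come along in ``per_fold``.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("features must be (n_samples, n_features) matching target")
    if folds.n != y.size:
        raise ValidationError("fold assignment does not cover all samples")
    oof = np.full(y.size, np.nan)
    rows = []
    for f in range(folds.k):
        test = folds.fold_of == f
        train = ~test
        if np.ptp(y[train]) == 0:
            raise DegenerateFoldError(f"fold {f}: constant training target")
        model = make_learner(learner_spec, hyper, seed)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        oof[test] = pred
        rows.append(
            {
                "fold": f,
                "n_test": int(test.sum()),
                "mae": mae(pred, y[test]),
                "rmse": rmse(pred, y[test]),
            }
        )
    per_fold = pd.DataFrame(rows)
    report = EvalReport.from_predictions(oof, y)
    fold_mean = {m: float(per_fold[m].mean()) for m in ("mae", "rmse")}
    fold_std = {m: float(per_fold[m].std(ddof=1)) for m in ("mae", "rmse")}
    return CvOutcome(oof_pred=oof, report=report, per_fold=per_fold,
                     fold_mean=fold_mean, fold_std=fold_std)
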