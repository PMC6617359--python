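"""Step 2 — fusing the simulated surface PM2.5 field with monitors.

The raw simulated concentration field carries a systematic low bias in
smoke (the sensitivity run under-represents fire emissions).  This module
learns the mapping from (simulated PM2.5, gap-filled AOD, meteorology,
space-time coordinates) to the monitor observations, scores it by 10-fold
cross-validation on the site-day table, refits on all monitors and applies
the model to every grid cell-day to produce a bias-corrected daily PM2.5
field.  Wind is encoded as speed plus (sin, cos) of direction to avoid the
0/360° discontinuity; predictions are clipped to be nonnegative.

Regional exposure summaries (area-weighted and population-weighted
averages) and the cross-method ensemble mean live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model_io import (
    FieldStack,
    MonitorTable,
    PopulationGrid,
    collocate,
)
from .errors import ValidationError
from .metrics_cv import (
    CvOutcome,
    EvalReport,
    FoldAssignment,
    kfold_split,
    make_learner,
    cross_validate,
)

__all__ = [
    "FUSION_FEATURES",
    "MIN_FUSION_ROWS",
    "FusionResult",
    "build_fusion_table",
    "fit_and_predict",
    "ensemble_mean",
    "area_weighted_average",
    "population_weighted_average",
    "percent_increase",
]

FUSION_FEATURES = [
    "pm25_sim",
    "aod_filled",
    "wind_speed",
    "wind_sin",
    "wind_cos",
    "t2",
    "rh2",
    "log_precip",
    "pblh",
    "day_index",
    "row",
    "col",
]

MIN_FUSION_ROWS = 100

_MET_REQUIRED = ("wind_u", "wind_v", "t2", "rh2", "log_precip", "pblh")


def _wind_encoding(u: np.ndarray, v: np.ndarray):
    speed = np.hypot(u, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin = np.where(speed > 0, v / speed, 0.0)
        cos = np.where(speed > 0, u / speed, 0.0)
    return speed, sin, cos


def _check_fusion_inputs(sens_sim: FieldStack, aod_filled: FieldStack,
                         met: dict[str, FieldStack]) -> None:
    missing = [k for k in _MET_REQUIRED if k not in met]
    if missing:
        raise ValidationError(f"missing fusion covariates: {missing}")
    ref = sens_sim
    for name, stack in [("aod_filled", aod_filled)] + [(k, met[k]) for k in _MET_REQUIRED]:
        if stack.values.shape != ref.values.shape or stack.dates != ref.dates:
            raise ValidationError(f"fusion covariate '{name}' grid/dates mismatch")


def build_fusion_table(monitors: MonitorTable, sens_sim: FieldStack,
                       aod_filled: FieldStack, met: dict[str, FieldStack]) -> pd.DataFrame:
    """One row per monitor site-day with complete features and the target.

    Rows with any missing feature value are dropped (and counted); a loud
    warning is raised if more than 20% of rows are lost.
    """
    _check_fusion_inputs(sens_sim, aod_filled, met)
    date_index = {d: i for i, d in enumerate(sens_sim.dates)}
    base = collocate(monitors, sens_sim).rename(columns={"field_value": "pm25_sim"})
    day_idx = base["date"].map(date_index).to_numpy()
    r = base["row"].to_numpy()
    c = base["col"].to_numpy()

    def at(stack: FieldStack) -> np.ndarray:
        return stack.values[day_idx, r, c]

    u = at(met["wind_u"])
    v = at(met["wind_v"])
    speed, sin, cos = _wind_encoding(u, v)
    table = base.assign(
        aod_filled=at(aod_filled),
        wind_speed=speed,
        wind_sin=sin,
        wind_cos=cos,
        t2=at(met["t2"]),
        rh2=at(met["rh2"]),
        log_precip=at(met["log_precip"]),
        pblh=at(met["pblh"]),
        day_index=day_idx.astype(float),
    )
    table["row"] = table["row"].astype(float)
    table["col"] = table["col"].astype(float)
    complete = table[FUSION_FEATURES + ["pm25_obs"]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if len(table) and n_dropped / len(table) > 0.20:
        warnings.warn(
            f"dropped {n_dropped}/{len(table)} site-day rows for missing features",
            stacklevel=2,
        )
    out = table[complete].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


@dataclass
class FusionResult:
    method: str
    corrected: FieldStack
    cv: CvOutcome
    hyper: dict
    seed: int


def fit_and_predict(features: pd.DataFrame, sens_sim: FieldStack,
                    aod_filled: FieldStack, met: dict[str, FieldStack],
                    method: str, hyper: dict | None = None, seed: int = 0,
                    folds: FoldAssignment | None = None, k: int = 10) -> FusionResult:
    """Cross-validate on the site-day table, refit on all rows, map to the grid."""
    _check_fusion_inputs(sens_sim, aod_filled, met)
    if len(features) < MIN_FUSION_ROWS:
        raise ValidationError(
            f"need >= {MIN_FUSION_ROWS} site-day rows to fuse, got {len(features)}"
        )
    X = features.loc[:, FUSION_FEATURES].to_numpy(dtype=np.float64)
    y = features["pm25_obs"].to_numpy(dtype=np.float64)
    if folds is None:
        folds = kfold_split(len(y), k=k, seed=seed)
    cv = cross_validate(X, y, method, folds, hyper=hyper, seed=seed)

    model = make_learner(method, hyper, seed)
    model.fit(X, y)

    n_days, n_rows, n_cols = sens_sim.values.shape
    ii, jj = np.mgrid[0:n_rows, 0:n_cols]
    corrected = np.empty_like(sens_sim.values)
    for d in range(n_days):
        u = met["wind_u"].values[d].ravel()
        v = met["wind_v"].values[d].ravel()
        speed, sin, cos = _wind_encoding(u, v)
        Xg = np.column_stack([
            sens_sim.values[d].ravel(),
            aod_filled.values[d].ravel(),
            speed, sin, cos,
            met["t2"].values[d].ravel(),
            met["rh2"].values[d].ravel(),
            met["log_precip"].values[d].ravel(),
            met["pblh"].values[d].ravel(),
            np.full(n_rows * n_cols, float(d)),
            ii.ravel().astype(float),
            jj.ravel().astype(float),
        ])
        corrected[d] = np.maximum(0.0, model.predict(Xg)).reshape(n_rows, n_cols)
    out = sens_sim.copy_with(corrected, name=f"pm25_fused_{method.lower()}")
    return FusionResult(method=method.lower(), corrected=out, cv=cv,
                        hyper=dict(hyper or {}), seed=seed)


def ensemble_mean(fields: dict[str, FieldStack] | list[FieldStack]) -> FieldStack:
    """Cellwise arithmetic mean of at least two method fields."""
    stacks = list(fields.values()) if isinstance(fields, dict) else list(fields)
    if len(stacks) < 2:
        raise ValidationError("ensemble mean needs at least 2 method fields")
    ref = stacks[0]
    for s in stacks[1:]:
        if s.values.shape != ref.values.shape or s.dates != ref.dates or s.grid != ref.grid:
            raise ValidationError("ensemble fields must share grid and dates")
    mean = np.mean([s.values for s in stacks], axis=0)
    return ref.copy_with(mean, name="pm25_fused_ensemble")


def area_weighted_average(stack: FieldStack) -> float:
    """Mean concentration over all cell-days (equal-area grid)."""
    return float(stack.values.mean())


def population_weighted_average(stack: FieldStack, pop: PopulationGrid) -> float:
    """Time-mean of the population-weighted spatial mean concentration."""
    if pop.grid.shape != stack.grid.shape:
        raise ValidationError("population grid does not match field grid")
    total = pop.pop.sum()
    if total <= 0:
        raise ValidationError("total population must be positive")
    daily = (stack.values * pop.pop).sum(axis=(1, 2)) / total
    return float(daily.mean())


def percent_increase(after: float, before: float) -> float:
    """Relative change in percent; report rounded to the nearest integer."""
    if before <= 0:
        raise ValidationError("percent_increase requires before > 0")
    return 100.0 * (after - before) / before
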