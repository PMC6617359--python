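"""Step 1 — gap filling of the cloud-masked satellite AOD raster.

Missing AOD pixels are predicted from the simulated AOD field plus
meteorological and geographic covariates (cloud fraction, cloud liquid
water content, water-vapor mixing ratio, terrain elevation, vegetation
cover) and the pixel's (day, row, col) coordinates, using one of three
learners: ordinary multi-linear regression (MLR), gradient boosting (GBM),
or random forest (RF).

Models are fitted per day (matching the per-day skill evaluation), with a
pooled all-days fallback when a day has fewer than 30 valid training
pixels.  Observed pixels always pass through unchanged; only masked pixels
receive predictions, clipped to be nonnegative.  Skill is reported per day
as spatial Pearson r and RMSE on an internal 80/20 holdout of valid
pixels, because in the real use case the truth at masked pixels is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import FieldStack, MaskedFieldStack
from .errors import ValidationError
from .metrics_cv import make_learner, pearson_r, rmse

__all__ = [
    "GAPFILL_FEATURES",
    "MIN_TRAIN_PIXELS",
    "TrainedFiller",
    "build_gapfill_features",
    "fit_filler",
    "gapfill_stack",
]

GAPFILL_FEATURES = [
    "aod_sim",
    "cloud_frac",
    "cloud_lwc",
    "qv",
    "elevation",
    "vegetation",
    "day_index",
    "row",
    "col",
]

MIN_TRAIN_PIXELS = 30

_MET_REQUIRED = ("cloud_frac", "cloud_lwc", "qv", "elevation", "vegetation")


class TooFewTrainingRows(ValidationError):
    """Raised when a day has too few valid pixels for a per-day model."""


@dataclass
class TrainedFiller:
    method: str
    model: object
    feature_names: list[str]
    scope: str          # "day:<i>" or "pooled"
    hyper: dict
    seed: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features.loc[:, self.feature_names].to_numpy(dtype=np.float64)
        return np.maximum(0.0, self.model.predict(X))


def _check_grids(aod_obs: MaskedFieldStack, aod_sim: FieldStack,
                 met: dict[str, FieldStack]) -> None:
    ref = aod_obs.base
    for name, stack in [("aod_sim", aod_sim)] + [(k, met[k]) for k in met]:
        if stack.values.shape != ref.values.shape:
            raise ValidationError(
                f"covariate '{name}' shape {stack.values.shape} does not match "
                f"AOD shape {ref.values.shape}"
            )
        if stack.dates != ref.dates:
            raise ValidationError(f"covariate '{name}' dates differ from AOD dates")
    missing = [k for k in _MET_REQUIRED if k not in met]
    if missing:
        raise ValidationError(f"missing gap-fill covariates: {missing}")


def build_gapfill_features(aod_obs: MaskedFieldStack, aod_sim: FieldStack,
                           met: dict[str, FieldStack], day: int) -> pd.DataFrame:
    """One row per grid cell for one day, flagged train (valid) vs fill.

    Columns: the gap-fill features, the target ``aod_obs`` (NaN on fill
    rows) and the boolean ``is_train``.
    """
    _check_grids(aod_obs, aod_sim, met)
    n_rows, n_cols = aod_obs.grid.shape
    ii, jj = np.mgrid[0:n_rows, 0:n_cols]
    valid = aod_obs.valid[day].ravel()
    df = pd.DataFrame({
        "aod_sim": aod_sim.values[day].ravel(),
        "cloud_frac": met["cloud_frac"].values[day].ravel(),
        "cloud_lwc": met["cloud_lwc"].values[day].ravel(),
        "qv": met["qv"].values[day].ravel(),
        "elevation": met["elevation"].values[day].ravel(),
        "vegetation": met["vegetation"].values[day].ravel(),
        "day_index": float(day),
        "row": ii.ravel().astype(float),
        "col": jj.ravel().astype(float),
        "aod_obs": np.where(valid, aod_obs.base.values[day].ravel(), np.nan),
        "is_train": valid,
    })
    return df


def fit_filler(features: pd.DataFrame, method: str, hyper: dict | None = None,
               seed: int = 0, scope: str = "day") -> TrainedFiller:
    """Fit one gap-fill model on the training rows of a feature table."""
    train = features[features["is_train"]]
    if len(train) < MIN_TRAIN_PIXELS:
        raise TooFewTrainingRows(
            f"only {len(train)} valid pixels; need >= {MIN_TRAIN_PIXELS}"
        )
    model = make_learner(method, hyper, seed)
    X = train.loc[:, GAPFILL_FEATURES].to_numpy(dtype=np.float64)
    y = train["aod_obs"].to_numpy(dtype=np.float64)
    model.fit(X, y)
    return TrainedFiller(method=method.lower(), model=model,
                         feature_names=list(GAPFILL_FEATURES), scope=scope,
                         hyper=dict(hyper or {}), seed=seed)


def gapfill_stack(aod_obs: MaskedFieldStack, aod_sim: FieldStack,
                  met: dict[str, FieldStack], method: str = "rf",
                  hyper: dict | None = None, seed: int = 0,
                  holdout_frac: float = 0.2) -> tuple[FieldStack, pd.DataFrame]:
    """Fill every masked pixel; return the filled stack and a per-day report.

    The report has columns ``day, date, n_valid, n_fill, holdout_r,
    holdout_rmse, pooled`` where the holdout metrics score an 80/20 split
    of that day's valid pixels.
    """
    _check_grids(aod_obs, aod_sim, met)
    n_days = aod_obs.base.n_days
    filled = aod_obs.base.values.copy()
    day_frames = [build_gapfill_features(aod_obs, aod_sim, met, d)
                  for d in range(n_days)]
    pooled_model: TrainedFiller | None = None
    rows = []
    for d, df in enumerate(day_frames):
        train = df[df["is_train"]]
        fill = df[~df["is_train"]]
        pooled = len(train) < MIN_TRAIN_PIXELS
        if pooled:
            if pooled_model is None:
                all_df = pd.concat(day_frames, ignore_index=True)
                pooled_model = fit_filler(all_df, method, hyper, seed, scope="pooled")
            model = pooled_model
            hold_r = hold_rmse = np.nan
            if len(train) >= 2:
                pred = model.predict(train)
                obs = train["aod_obs"].to_numpy()
                try:
                    hold_r = pearson_r(pred, obs)
                except Exception:
                    hold_r = np.nan
                hold_rmse = rmse(pred, obs)
        else:
            rng = np.random.default_rng([seed, d])
            perm = rng.permutation(len(train))
            n_hold = max(1, int(round(holdout_frac * len(train))))
            hold_idx = train.index[perm[:n_hold]]
            sub = df.copy()
            sub.loc[hold_idx, "is_train"] = False
            model_h = fit_filler(sub, method, hyper, seed, scope=f"day:{d}")
            pred = model_h.predict(df.loc[hold_idx])
            obs = df.loc[hold_idx, "aod_obs"].to_numpy()
            try:
                hold_r = pearson_r(pred, obs)
            except Exception:
                hold_r = np.nan
            hold_rmse = rmse(pred, obs)
            # refit on all valid pixels of the day for the actual fill
            model = fit_filler(df, method, hyper, seed, scope=f"day:{d}")
        if len(fill):
            pred_fill = model.predict(fill)
            flat = filled[d].ravel()
            flat[~df["is_train"].to_numpy()] = pred_fill
            filled[d] = flat.reshape(filled[d].shape)
        rows.append({
            "day": d,
            "date": aod_obs.base.dates[d],
            "n_valid": int(len(train)),
            "n_fill": int(len(fill)),
            "holdout_r": hold_r,
            "holdout_rmse": hold_rmse,
            "pooled": pooled,
        })
    out = aod_obs.base.copy_with(filled, name="aod_filled")
    return out, pd.DataFrame(rows)
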