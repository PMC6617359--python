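"""Synthetic smoke-episode scene generator.

Builds a complete, self-consistent synthetic world with the statistical
structure the fusion/assessment pipeline assumes:

* a smooth regional background PM2.5 field plus a handful of wildfire
  point sources whose Gaussian plumes are advected daily by a scene wind
  and ramp up and down over the episode (triangular emission profile);
* a paired pair of model runs: ``ctrl_sim`` (non-fire sources only) and
  ``sens_sim`` (fire + non-fire), where the fire contribution in the
  sensitivity run is deliberately scaled down by a bias factor γ ∈ (0, 1]
  so the simulation systematically under-predicts smoke — the bias the
  fusion step must learn away;
* a linear AOD proxy (``aod = a + b · PM2.5``) observed through
  multiplicative retrieval noise and masked by clouds so that a target
  fraction of pixels is missing;
* surface monitors placed preferentially in populated cells, observing
  truth through mean-one lognormal noise;
* population (urban lognormal bumps over a rural floor), a rectangular
  county partition, and county baseline mortality proportional to
  population.

Everything is a pure function of ``SceneParams`` including its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .data_model_io import (
    CountyRaster,
    FieldStack,
    Grid,
    MaskedFieldStack,
    MonitorTable,
    MortalityTable,
    PopulationGrid,
    read_county_raster,
    read_field_stack,
    read_masked_field_stack,
    read_monitor_csv,
    read_mortality_csv,
    read_population,
    write_county_raster,
    write_field_stack,
    write_masked_field_stack,
    write_monitor_csv,
    write_mortality_csv,
    write_population,
)
from .errors import ParameterError

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "simulate_scene",
    "scene_missing_fraction",
    "write_scene",
    "read_scene",
    "MET_NAMES",
]

MET_NAMES = (
    "wind_u",
    "wind_v",
    "t2",
    "rh2",
    "log_precip",
    "pblh",
    "cloud_frac",
    "cloud_lwc",
    "qv",
    "elevation",
    "vegetation",
)


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the synthetic world; the seed fully determines the scene."""

    n_rows: int = 60
    n_cols: int = 60
    n_days: int = 31
    n_fires: int = 3
    fire_strength: float = 150.0       # peak plume amplitude, μg m^-3
    plume_sigma: float = 4.0           # Gaussian plume width, cells
    advection_speed: float = 2.0       # cells day^-1
    background_mean: float = 3.0       # μg m^-3
    fire_bias_factor: float = 0.5      # γ: fire term scale in the SENS run
    obs_noise_cv: float = 0.10         # monitor noise coefficient of variation
    aod_slope: float = 0.02            # b, AOD per μg m^-3
    aod_intercept: float = 0.05        # a
    cloud_cover_target: float = 0.55   # target AOD missingness fraction
    n_monitors: int = 50
    n_counties: int = 25
    death_rate: float = 2.4e-5         # deaths person^-1 day^-1
    seed: int = 0
    # secondary noise/texture knobs
    model_noise_cv: float = 0.10       # multiplicative error of CTRL/SENS runs
    aod_noise_cv: float = 0.05         # multiplicative AOD retrieval noise
    background_noise_sd: float = 1.0   # spatial texture of the background, μg m^-3
    smooth_width: float = 3.0          # Gaussian kernel width for smooth fields, cells
    n_pop_centers: int = 5
    urban_peak_pop: float = 30000.0    # persons per cell at an urban center
    rural_floor_pop: float = 50.0      # persons per cell
    start_date: str = "2017-08-15"

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ParameterError("grid must be at least 2x2")
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")
        if self.n_fires < 0:
            raise ParameterError("n_fires must be >= 0")
        if not (0.0 < self.fire_bias_factor <= 1.0):
            raise ParameterError("fire_bias_factor must be in (0, 1]")
        if not (0.0 <= self.cloud_cover_target < 1.0):
            raise ParameterError(
                "cloud_cover_target must be in [0, 1); full cloud cover leaves "
                "no valid AOD pixels to train on"
            )
        n_cells = self.n_rows * self.n_cols
        if not (1 <= self.n_monitors <= n_cells):
            raise ParameterError("n_monitors must be in [1, n_cells]")
        if not (1 <= self.n_counties <= n_cells):
            raise ParameterError("n_counties must be in [1, n_cells]")
        for name in ("obs_noise_cv", "model_noise_cv", "aod_noise_cv",
                     "background_noise_sd", "death_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.fire_strength < 0 or self.plume_sigma <= 0:
            raise ParameterError("fire_strength >= 0 and plume_sigma > 0 required")

    @property
    def grid(self) -> Grid:
        return Grid(self.n_rows, self.n_cols)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        return cls(**d)


@dataclass
class SyntheticScene:
    params: SceneParams
    truth: FieldStack
    background: FieldStack
    fire: FieldStack
    ctrl_sim: FieldStack
    sens_sim: FieldStack
    aod_true: FieldStack
    aod_sim: FieldStack
    aod_obs: MaskedFieldStack
    met: dict[str, FieldStack]
    monitors: MonitorTable
    population: PopulationGrid
    counties: CountyRaster
    mortality: MortalityTable

    @property
    def grid(self) -> Grid:
        return self.truth.grid

    @property
    def dates(self):
        return self.truth.dates


def _smooth2d(rng: np.random.Generator, shape, width: float) -> np.ndarray:
    """Unit-variance smooth random field (white noise ⊛ Gaussian kernel)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=width, mode="reflect")
    return (f - f.mean()) / f.std()


def _smooth3d(rng: np.random.Generator, n_days: int, shape, width: float) -> np.ndarray:
    return np.stack([_smooth2d(rng, shape, width) for _ in range(n_days)])


def _lognormal_mean_one(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with E[factor] = 1 and sd/mean = cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def _triangular_ramp(n_days: int) -> np.ndarray:
    """Emission strength profile: 0→1→0 over the episode, peak at mid-period."""
    if n_days == 1:
        return np.ones(1)
    t = np.arange(n_days)
    mid = (n_days - 1) / 2.0
    return 1.0 - np.abs(t - mid) / mid


def _partition_counties(n_rows: int, n_cols: int, n_counties: int) -> np.ndarray:
    bands = max(1, int(np.floor(np.sqrt(n_counties))))
    if bands > n_rows:
        raise ParameterError("too many counties for grid rows")
    per_band = [n_counties // bands + (1 if i < n_counties % bands else 0)
                for i in range(bands)]
    if max(per_band) > n_cols:
        raise ParameterError("too many counties for grid columns")
    row_edges = np.linspace(0, n_rows, bands + 1).astype(int)
    county_id = np.empty((n_rows, n_cols), dtype=np.int64)
    next_id = 0
    for b, k in enumerate(per_band):
        col_edges = np.linspace(0, n_cols, k + 1).astype(int)
        for j in range(k):
            county_id[row_edges[b]:row_edges[b + 1], col_edges[j]:col_edges[j + 1]] = next_id
            next_id += 1
    return county_id


def simulate_scene(params: SceneParams) -> SyntheticScene:
    """Generate the full synthetic scene; deterministic given ``params.seed``."""
    p = params
    grid = p.grid
    shape2 = (p.n_rows, p.n_cols)
    rng = np.random.default_rng(p.seed)
    dates = tuple(pd.date_range(p.start_date, periods=p.n_days).date)
    ii, jj = np.mgrid[0:p.n_rows, 0:p.n_cols]

    # (1) background: mean + smooth spatial texture, floored at 0
    background2d = np.maximum(
        0.0, p.background_mean + p.background_noise_sd * _smooth2d(rng, shape2, p.smooth_width)
    )
    background = np.broadcast_to(background2d, (p.n_days,) + shape2).copy()

    # (2) scene wind and advected fire plumes with a triangular emission ramp
    theta = rng.uniform(0.0, 2.0 * np.pi)
    wind_x = p.advection_speed * np.cos(theta)   # column direction
    wind_y = p.advection_speed * np.sin(theta)   # row direction
    margin = min(10, p.n_rows // 4, p.n_cols // 4)
    fire_rows = rng.integers(margin, p.n_rows - margin, size=p.n_fires)
    fire_cols = rng.integers(margin, p.n_cols - margin, size=p.n_fires)
    ramp = _triangular_ramp(p.n_days)
    fire = np.zeros((p.n_days,) + shape2)
    for t in range(p.n_days):
        # integer-rounded cumulative displacement of each plume center
        di = int(np.rint(t * wind_y))
        dj = int(np.rint(t * wind_x))
        for f in range(p.n_fires):
            ci = fire_rows[f] + di
            cj = fire_cols[f] + dj
            amp = p.fire_strength * ramp[t]
            if amp == 0.0:
                continue
            d2 = (ii - ci) ** 2 + (jj - cj) ** 2
            fire[t] += amp * np.exp(-d2 / (2.0 * p.plume_sigma**2))

    # (3) truth
    truth = background + fire

    # (4, 5) model runs share one multiplicative error realization, so the
    # no-fire limit gives ctrl_sim == sens_sim exactly
    model_noise = 1.0 + p.model_noise_cv * _smooth3d(rng, p.n_days, shape2, p.smooth_width)
    ctrl_sim = np.maximum(0.0, background * model_noise)
    sens_sim = np.maximum(0.0, (background + p.fire_bias_factor * fire) * model_noise)

    # (6) AOD link, retrieval noise, cloud mask at the target missingness
    aod_true = p.aod_intercept + p.aod_slope * truth
    aod_sim = p.aod_intercept + p.aod_slope * sens_sim
    aod_vals = aod_true * _lognormal_mean_one(rng, p.aod_noise_cv, aod_true.shape)
    cloud_frac = norm.cdf(_smooth3d(rng, p.n_days, shape2, p.smooth_width))
    if p.cloud_cover_target == 0.0:
        valid = np.ones_like(cloud_frac, dtype=bool)
    else:
        threshold = np.quantile(cloud_frac, 1.0 - p.cloud_cover_target)
        valid = cloud_frac <= threshold
    aod_vals = np.where(valid, aod_vals, np.nan)  # NaN sentinel at masked pixels

    # (8) population: urban lognormal bumps on a rural floor
    pop = np.full(shape2, p.rural_floor_pop)
    center_rows = rng.integers(0, p.n_rows, size=p.n_pop_centers)
    center_cols = rng.integers(0, p.n_cols, size=p.n_pop_centers)
    amps = p.urban_peak_pop * rng.lognormal(mean=0.0, sigma=0.5, size=p.n_pop_centers)
    for k in range(p.n_pop_centers):
        d2 = (ii - center_rows[k]) ** 2 + (jj - center_cols[k]) ** 2
        pop += amps[k] * np.exp(-d2 / (2.0 * 3.0**2))

    # (7) monitors: distinct cells sampled proportional to population;
    # observations are truth through mean-one lognormal noise (unbiased)
    prob = (pop / pop.sum()).ravel()
    cells = rng.choice(pop.size, size=p.n_monitors, replace=False, p=prob)
    mon_rows, mon_cols = np.unravel_index(cells, shape2)
    noise = _lognormal_mean_one(rng, p.obs_noise_cv, (p.n_monitors, p.n_days))
    records = []
    for m in range(p.n_monitors):
        sid = f"S{m:03d}"
        for t, date in enumerate(dates):
            records.append(
                (sid, int(mon_rows[m]), int(mon_cols[m]), date,
                 truth[t, mon_rows[m], mon_cols[m]] * noise[m, t])
            )
    monitors = MonitorTable.from_records(records, grid)

    # (9, 10) counties and baseline mortality proportional to population
    county_id = _partition_counties(p.n_rows, p.n_cols, p.n_counties)
    county_pop = np.bincount(county_id.ravel(), weights=pop.ravel(),
                             minlength=p.n_counties)
    mortality = MortalityTable(pd.DataFrame({
        "county_id": np.arange(p.n_counties),
        "daily_deaths": county_pop * p.death_rate,
    }))

    # meteorological covariates (wind reflects the advection vector; the
    # rest are smooth plausible fields uncorrelated with the plumes)
    met_arrays = {
        "wind_u": wind_x + 0.5 * _smooth3d(rng, p.n_days, shape2, p.smooth_width),
        "wind_v": wind_y + 0.5 * _smooth3d(rng, p.n_days, shape2, p.smooth_width),
        "t2": 295.0 + 5.0 * _smooth3d(rng, p.n_days, shape2, p.smooth_width),
        "rh2": np.clip(50.0 + 15.0 * _smooth3d(rng, p.n_days, shape2, p.smooth_width), 2.0, 100.0),
        "pblh": np.maximum(100.0, 800.0 + 300.0 * _smooth3d(rng, p.n_days, shape2, p.smooth_width)),
        "cloud_frac": cloud_frac,
        "qv": np.maximum(0.1, 8.0 + 2.0 * _smooth3d(rng, p.n_days, shape2, p.smooth_width)),
        "elevation": np.broadcast_to(
            np.maximum(0.0, 500.0 + 400.0 * _smooth2d(rng, shape2, p.smooth_width)),
            (p.n_days,) + shape2).copy(),
        "vegetation": np.broadcast_to(
            np.clip(0.5 + 0.25 * _smooth2d(rng, shape2, p.smooth_width), 0.0, 1.0),
            (p.n_days,) + shape2).copy(),
    }
    precip = np.maximum(0.0, 1.5 * _smooth3d(rng, p.n_days, shape2, p.smooth_width))
    met_arrays["log_precip"] = np.log(precip + 0.01)
    met_arrays["cloud_lwc"] = cloud_frac * np.maximum(
        0.0, 0.2 + 0.1 * _smooth3d(rng, p.n_days, shape2, p.smooth_width))

    def fs(name, arr):
        return FieldStack(grid, dates, arr, name)

    met = {name: fs(name, met_arrays[name]) for name in MET_NAMES}
    return SyntheticScene(
        params=p,
        truth=fs("pm25_truth", truth),
        background=fs("pm25_background", background),
        fire=fs("pm25_fire", fire),
        ctrl_sim=fs("pm25_ctrl", ctrl_sim),
        sens_sim=fs("pm25_sens", sens_sim),
        aod_true=fs("aod_true", aod_true),
        aod_sim=fs("aod_sim", aod_sim),
        aod_obs=MaskedFieldStack(fs("aod_obs", aod_vals), valid),
        met=met,
        monitors=monitors,
        population=PopulationGrid(grid, pop),
        counties=CountyRaster(grid, county_id),
        mortality=mortality,
    )


def scene_missing_fraction(scene: SyntheticScene) -> np.ndarray:
    """Fraction of invalid (cloud-masked) AOD pixels for each day."""
    return scene.aod_obs.missing_fraction()


# ---------------------------------------------------------------------------
# Scene persistence (one directory, NetCDF + CSV + YAML)


def write_scene(scene: SyntheticScene, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr in ("truth", "background", "fire", "ctrl_sim", "sens_sim",
                 "aod_true", "aod_sim"):
        write_field_stack(getattr(scene, attr), out / f"{attr}.nc")
    write_masked_field_stack(scene.aod_obs, out / "aod_obs.nc")
    for name, stack in scene.met.items():
        write_field_stack(stack, out / f"met_{name}.nc")
    write_monitor_csv(scene.monitors, out / "monitors.csv")
    write_population(scene.population, out / "population.nc")
    write_county_raster(scene.counties, out / "counties.nc")
    write_mortality_csv(scene.mortality, out / "mortality.csv")
    (out / "params.yaml").write_text(yaml.safe_dump(scene.params.to_dict()))


def read_scene(in_dir) -> SyntheticScene:
    from pathlib import Path

    src = Path(in_dir)
    params = SceneParams.from_dict(yaml.safe_load((src / "params.yaml").read_text()))
    stacks = {attr: read_field_stack(src / f"{attr}.nc")
              for attr in ("truth", "background", "fire", "ctrl_sim", "sens_sim",
                           "aod_true", "aod_sim")}
    grid = stacks["truth"].grid
    return SyntheticScene(
        params=params,
        aod_obs=read_masked_field_stack(src / "aod_obs.nc"),
        met={name: read_field_stack(src / f"met_{name}.nc") for name in MET_NAMES},
        monitors=read_monitor_csv(src / "monitors.csv", grid),
        population=read_population(src / "population.nc"),
        counties=read_county_raster(src / "counties.nc"),
        mortality=read_mortality_csv(src / "mortality.csv"),
        **stacks,
    )
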