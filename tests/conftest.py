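"""Shared fixtures: scenes are generated once per session and reused."""

import numpy as np
import pytest
from hypothesis import settings

from smokefuse.data_model_io import FieldStack, Grid
from smokefuse.scene_sim import SceneParams, simulate_scene

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_scene():
    """The default 60x60x31 synthetic episode, seed 1."""
    return simulate_scene(SceneParams(seed=1))


@pytest.fixture(scope="session")
def small_scene():
    """A light scene for fast structural tests."""
    return simulate_scene(SceneParams(
        n_rows=24, n_cols=24, n_days=8, n_fires=2, n_monitors=20,
        n_counties=9, seed=7))


@pytest.fixture()
def tiny_grid():
    return Grid(4, 5)


@pytest.fixture()
def tiny_stack(tiny_grid):
    import pandas as pd

    dates = tuple(pd.date_range("2017-08-15", periods=3).date)
    vals = np.zeros((3, 4, 5))
    return FieldStack(tiny_grid, dates, vals, "pm25_test")


@pytest.fixture(scope="session")
def default_gapfill(default_scene):
    """RF gap fill of the default scene (shared: it is the slow stage)."""
    from smokefuse.aod_gapfill import gapfill_stack

    filled, report = gapfill_stack(
        default_scene.aod_obs, default_scene.aod_sim, default_scene.met,
        method="rf", seed=2)
    return filled, report


@pytest.fixture(scope="session")
def default_fusion(default_scene, default_gapfill):
    """MLR/GBM/RF fusion of the default scene with 10-fold CV."""
    from smokefuse.pm25_fusion import build_fusion_table, fit_and_predict

    filled, _ = default_gapfill
    table = build_fusion_table(
        default_scene.monitors, default_scene.sens_sim, filled, default_scene.met)
    results = {}
    for method in ("mlr", "gbm", "rf"):
        results[method] = fit_and_predict(
            table, default_scene.sens_sim, filled, default_scene.met,
            method=method, seed=3, k=10)
    return table, results
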