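# smokefuse

Wildfire smoke episodes drive surface fine-particulate (PM2.5) levels far
above anything routine monitoring networks or chemical-transport models
capture well on their own: models place the smoke but systematically
mis-estimate its amount, satellites see the aerosol column only where there
are no clouds, and ground monitors are sparse. `smokefuse` implements a
two-step machine-learning data-integration pipeline that combines all
three — plus the downstream health impact assessment that turns the fused
exposure field into attributable-mortality estimates. It is written for
air-quality and environmental-health researchers who want a tested,
seed-reproducible implementation of this workflow, exercised end to end on
synthetic smoke scenes.

## The method

**Step 1 — AOD gap filling.** The satellite aerosol optical depth (AOD)
raster is missing wherever clouds block the retrieval (often more than half
the domain during a smoke episode). Missing pixels are predicted from the
model-simulated AOD, cloud fraction, cloud liquid water content, water-vapor
mixing ratio, terrain elevation, vegetation cover and the pixel's
space-time coordinates, using multi-linear regression (MLR,
`y = α + Σ_k β_k x_k + ε`), gradient boosting (GBM), or random forest (RF).
Observed pixels always pass through unchanged.

**Step 2 — PM2.5 fusion.** The simulated surface PM2.5 field is
bias-corrected against ground monitors: a learner maps (simulated PM2.5,
gap-filled AOD, wind, temperature, humidity, log precipitation, boundary-
layer height, space-time coordinates) to the observed site-day PM2.5, is
scored by 10-fold cross-validation (MAE, fractional bias FB, R², RMSE),
then refit on all monitors and applied to every grid cell-day. A
cross-method ensemble mean and area-/population-weighted regional exposure
averages are computed from the corrected fields.

**Health impact assessment.** Attributable multiple-cause mortality follows
the thresholded exposure-response sum

    deaths = Σ_cells Σ_intervals D × M × (RR(C) − 1)

with 1 μg m⁻³ concentration intervals between 5 and 200 μg m⁻³ (cell-days
below 5 are excluded, above 200 capped), county mortality `M` downscaled to
the grid proportionally to population, and a linear relative-risk function
RR(C) = 1 + β·C with β = 0.0011 (95% CI: 0, 0.0026) per μg m⁻³. Pairing the
fused all-source field with a non-fire control run apportions both exposure
and mortality into fire and non-fire shares; the 5 μg m⁻³ floor makes the
fire share of mortality exceed its share of concentration whenever the
non-fire background alone falls below the floor.

Because no real model output, satellite retrievals or monitor records ship
with the package, a synthetic scene generator (`smokefuse.scene_sim`)
produces gridded worlds with the structure the method assumes: advected
Gaussian fire plumes over a smooth background, a deliberately fire-biased
simulation pair (CTRL/SENS), a linear AOD proxy with cloud-driven
missingness, population-sited noisy monitors, and county mortality
proportional to population.

## Worked example

```python
from smokefuse.cli_runner import RunConfig, run_all

manifest = run_all(RunConfig(seed=1), log=print)
```

prints (about six minutes on one CPU):

```
simulate: 60x60x31 seed=1
gapfill: method=rf
raw SENS vs monitors: FB=-39.0% RMSE=10.55
fusion table: 1550 rows (0 dropped)
fuse[mlr]: CV FB=0.0% RMSE=3.26 R2=0.97
fuse[gbm]: CV FB=0.5% RMSE=3.70 R2=0.97
fuse[rf]: CV FB=-0.1% RMSE=3.59 R2=0.97
hia[rf]: 54.3 deaths (CI 0.0, 128.2)
attribution: fire 66% of exposure, 98% of mortality
```

Reading the numbers: the raw simulated field under-predicts the monitors by
39% (fractional bias), because the scene's sensitivity run carries only half
the true fire contribution. After fusion the cross-validated bias is within
half a percent for every learner and the RMSE drops roughly threefold. The
assessment then attributes 54 deaths (95% CI 0–128, from the risk-slope CI)
to the episode's PM2.5 on this synthetic scene, and the fire share of
mortality (98%) exceeds the fire share of population-weighted exposure
(66%) — the signature of the 5 μg m⁻³ exposure-response floor, since the
non-fire background sits almost entirely below it.

The same chain is available from the shell:

```sh
smokefuse simulate --seed 1 --out scene/
smokefuse gapfill --scene scene/ --method rf --seed 2 --out aod_filled.nc
smokefuse fuse --scene scene/ --aod aod_filled.nc --methods mlr,gbm,rf --seed 3 --out fused/
smokefuse run --seed 1 --out run_dir/       # everything, with a manifest
```

## Layout

| module | contents |
| --- | --- |
| `smokefuse.data_model_io` | grid/field/monitor/county containers, NetCDF + CSV I/O, collocation |
| `smokefuse.scene_sim` | synthetic scene generator and persistence |
| `smokefuse.metrics_cv` | MAE/FB/R²/RMSE, k-fold harness, learner registry |
| `smokefuse.aod_gapfill` | Step 1: per-day AOD gap filling with holdout skill report |
| `smokefuse.pm25_fusion` | Step 2: monitor fusion, ensemble, regional averages |
| `smokefuse.hia` | downscaling, exposure histogram, attributable mortality, attribution |
| `smokefuse.cli_runner` | `run_all` orchestration and the `smokefuse` CLI |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
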