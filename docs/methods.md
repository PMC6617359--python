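# Methods

This note documents the models, parameter choices and numerical decisions
behind `smokefuse`, and what its synthetic tests do and do not demonstrate
about real data.

## The synthetic scene

The generator (`scene_sim.simulate_scene`) builds the smallest world in
which the two-step fusion pipeline and the health assessment are all
identifiable and testable. Its construction, in order:

1. **Background.** A static spatial background
   `max(0, μ_bg + σ_bg · S)` with `μ_bg = 3 μg m⁻³`,
   `σ_bg = 1 μg m⁻³`, where `S` is a unit-variance smooth random field
   (Gaussian white noise convolved with a 3-cell Gaussian kernel). The
   3 μg m⁻³ level matches non-fire-season regional background PM2.5 in the
   western-US literature.
2. **Fires.** `n_fires = 3` point sources at random interior cells. Each
   carries a Gaussian plume of width `plume_sigma = 4` cells whose center
   is advected by the scene wind (speed 2 cells day⁻¹, random direction,
   integer-rounded cumulative displacement — no interpolation scheme is
   invented) and whose amplitude follows a triangular ramp peaking at
   `fire_strength = 150 μg m⁻³` mid-episode. Truth = background + plumes.
3. **Model runs.** `ctrl_sim = background · (1 + ε)` and
   `sens_sim = (background + γ · plumes) · (1 + ε)` share one smooth
   multiplicative error realization `ε` (cv 0.10), so with no fires the two
   runs are identical. The fire-bias factor `γ = 0.5` makes the
   sensitivity run under-predict smoke by the −40%-class fractional bias
   that motivates the fusion step. The 10% model-error magnitude is a
   deliberately mild stand-in for transport/emission error; real
   chemical-transport errors are larger and, crucially, spatially
   structured (see Limitations).
4. **AOD.** `aod = 0.05 + 0.02 · PM2.5`, a linear proxy with spatially
   constant coefficients — the simplest structure under which both steps
   can provably recover the signal. The observed raster is the true AOD
   under mean-one multiplicative retrieval noise (cv 0.05, the
   expected-error class of modern satellite AOD products), masked where a
   per-day smooth cloud-fraction field exceeds the pooled quantile that
   yields `cloud_cover_target = 0.55` missingness — slightly more than
   half the domain, as heavy smoke episodes show.
5. **Monitors.** 50 distinct cells sampled with probability proportional
   to population observe truth through mean-one lognormal noise
   (cv 0.10). The σ²/2 correction makes them unbiased: over the 1550
   site-days of the default scene, mean(obs/truth) stays within 3% of 1.
6. **Population, counties, mortality.** Five lognormal urban bumps
   (peak ≈ 3·10⁴ persons/cell, i.e. ≈ 2·10³ km⁻² at 4-km cells) on a
   50 persons/cell rural floor give ≈ 10⁷ people; a rectangular partition
   into 25 counties and a crude death rate of 2.4·10⁻⁵ person⁻¹ day⁻¹
   (the US all-cause rate) yield ≈ 240 baseline deaths day⁻¹.

Everything is a pure function of the seed; scenes are byte-identical across
runs.

## Step 1: gap filling

Features per pixel: simulated AOD, cloud fraction, cloud liquid water,
water-vapor mixing ratio, elevation, vegetation, and (day, row, col).
Models are fitted **per day**, matching the per-day evaluation of gap-fill
skill; a day with fewer than 30 valid pixels falls back to a pooled
all-days model (logged in the report). Skill is reported as spatial Pearson
r and RMSE on an internal 80/20 holdout of valid pixels — in production the
truth at masked pixels is unknowable, so the holdout is the only honest
skill estimate. Observed pixels pass through bit-exactly; predictions are
clipped to ≥ 0.

Learner defaults (shared with Step 2): RF with 500 fully grown trees and
√p feature subsetting; GBM with up to 1000 depth-3 trees, learning rate
0.05, early stopping on a 20% validation slice; MLR is ordinary least
squares. These are the standard defaults of the respective algorithms; no
problem-specific tuning is baked in, though a hyperparameter dict can be
passed everywhere.

A known tree limitation: in the noiseless `γ = 1` limit MLR reproduces the
true AOD to machine precision at masked pixels, but RF/GBM cannot
extrapolate above the training range, so days where cloud blobs cover the
plume cores (the highest AOD in the domain) show depressed tree skill.
Relatedly, because the scene's simulation bias is purely multiplicative in
amplitude and Pearson correlation is scale-invariant, the simulated AOD
retains ~0.99 spatial correlation with truth, and gap-filled fields improve
on it in RMSE but not reliably in correlation. On real retrievals the
model's AOD errors are spatially structured (misplaced plumes), which is
where learned gap filling earns its correlation gains; the synthetic scene
cannot show that.

## Step 2: fusion

The site-day table pairs each monitor observation with the simulated
PM2.5, the gap-filled AOD and six meteorological covariates at its host
cell; wind enters as speed plus (sin θ, cos θ) to avoid the 0/360°
discontinuity, precipitation as log(precip + 0.01). Rows with missing
features are dropped and counted (a warning fires above 20%).

Cross-validation partitions site-day samples into k = 10 random near-equal
folds; each sample is predicted by a model never trained on it. The
primary report uses pooled out-of-fold predictions; per-fold mean ± sd is
emitted alongside since "averaging the validation results" is ambiguous
between the two. Site-blocked CV is deliberately not the default: the
production question is interpolation to unmonitored cells within the same
network's domain, but the harness accepts any externally supplied fold
assignment. Metric conventions: FB is the means-based air-quality form
`200·(P̄−Ō)/(P̄+Ō)`; R² is squared Pearson correlation (the out-of-sample
fusion convention); the paired-FB and coefficient-of-determination variants
sit behind flags.

The final model refits on all rows and predicts every cell-day, clipped to
≥ 0. On the default scene this removes the −39% raw bias to within ±1% for
every learner and cuts RMSE roughly threefold. One structural caveat: with
an exactly linear AOD–PM2.5 link, OLS on the gap-filled AOD is the
correctly specified model, so MLR attains the lowest CV RMSE on the
synthetic scene; the real-world advantage of the tree ensembles rests on
nonlinearity that the scene deliberately omits.

## Health impact assessment

The exposure histogram bins each cell-day into 1 μg m⁻³ intervals over
[5, 200] μg m⁻³: values below 5 are excluded, values above 200 are capped
into the top interval. The histogram also accumulates the per-interval sum
of capped concentrations, and the relative risk of an interval is evaluated
at its **within-interval mean concentration**. For the default linear RR
this makes the histogram sum *identical* to the direct per-cell-day
summation (the mean commutes with an affine RR), eliminating discretization
bias entirely; the conventional midpoint evaluation is available via
`representative="midpoint"` and differs by at most the half-bin width
(≤ 0.5 μg m⁻³, under 2% here). For the log-linear RR form the mean-point
evaluation carries a convexity error bounded by the within-bin variance —
negligible at 1 μg m⁻³ bins.

The excess-death form is `M·(RR − 1)` exactly; with RR referenced at zero
concentration (`RR(c) = 1 + 0.0011·c`), the reference level being a
configuration flag (`baseline="c_min"` shifts it to the 5 μg m⁻³ floor and
lowers totals by the constant `β·c_min` term per included cell-day).
Downscaling allocates county deaths proportionally to cell population and
conserves county totals exactly (tested to 1e-12 relative); CI bounds
re-evaluate the sum at the slope's CI endpoints, which brackets the point
estimate because the sum is monotone in β.

Attribution floors the cellwise fused-minus-control difference at zero
(counted and reported) before population weighting. The mortality share
re-runs the full exposure-response sum on both fields, so the 5 μg m⁻³
floor amplifies the fire mortality share above the fire concentration
share whenever the control field sits below the floor over populated
cells — on the default scene, 66% of exposure vs 98% of mortality.

## Numerical and design notes

- NetCDF I/O uses the classic (NetCDF3) format via xarray's scipy backend;
  float64 round trips are bit-exact, invalid AOD pixels are NaN with a
  companion `<name>_valid` byte mask.
- Monitor/mortality CSVs are re-read with round-trip float parsing so file
  persistence is lossless.
- Monitors are pinned to host cells by integer (row, col); no projection
  machinery, no sub-cell interpolation.
- The orchestrator fans one global seed out additively (scene s, gap fill
  s+1, fusion s+2) so a single integer reproduces a run.
- Default problem size (60×60 cells × 31 days, 50 monitors) was chosen so
  a full pipeline run completes in a few minutes on one CPU while leaving
  every stage's statistics well-resolved (1550 CV samples, ~2000 valid
  AOD pixels per day).

## Limitations

- The scene's model error is multiplicative and spatially smooth; real
  chemical-transport error includes plume displacement and timing errors.
  Consequently the synthetic world understates what gap filling adds in
  correlation terms and overstates how well a linear fusion model can do.
- The AOD–PM2.5 link is linear with constant coefficients; real links vary
  with boundary-layer depth, humidity and aerosol type.
- Daily resolution throughout; the hourly-to-daily averaging of real
  monitor networks (and any completeness rule, e.g. ≥ 75% of hours) is
  upstream of this package and not modelled.
- The risk function is a single all-ages, all-cause short-term slope; no
  age stratification, morbidity endpoints, or long-term effects.
- Passing tests on synthetic scenes demonstrate correctness of the
  machinery and recoverability under the stated assumptions — not skill on
  any real episode.
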