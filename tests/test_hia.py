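"""Exposure-response mortality: downscaling, binning, Eq-style attribution.

The independent oracle here is a per-day, per-cell brute-force summation:
for every cell-day, skip concentrations below the floor, cap at the
ceiling, and accumulate M * (RR(c) - 1) directly, without the histogram.
"""

import numpy as np
import pandas as pd
import pytest

from smokefuse.data_model_io import (
    CountyRaster,
    FieldStack,
    Grid,
    MortalityTable,
    PopulationGrid,
)
from smokefuse.errors import UndefinedMetricError, ValidationError
from smokefuse.hia import (
    GriddedMortalityBaseline,
    RiskFunction,
    attributable_mortality,
    downscale_mortality,
    exposure_histogram,
    relative_risk,
    source_attribution,
)

DATES = tuple(pd.date_range("2017-08-15", periods=3).date)


def brute_force_deaths(values, m_cell, risk, beta=None):
    """Independent per-day per-cell summation of excess deaths."""
    beta = risk.beta if beta is None else beta
    b0 = 0.0 if risk.baseline == "zero" else risk.c_min
    total = 0.0
    n_days, n_rows, n_cols = values.shape
    for t in range(n_days):
        for i in range(n_rows):
            for j in range(n_cols):
                c = values[t, i, j]
                if c < risk.c_min:
                    continue
                c = min(c, risk.c_max)
                if risk.form == "linear":
                    rr = 1.0 + beta * (c - b0)
                else:
                    rr = np.exp(beta * (c - b0))
                total += m_cell[i, j] * (rr - 1.0)
    return total


def stack_of(values, grid=None):
    values = np.asarray(values, dtype=float)
    grid = grid or Grid(*values.shape[1:])
    return FieldStack(grid, DATES[: values.shape[0]], values, "pm25_exposure")


class TestDownscaleMortality:
    def test_proportional_allocation_hand_case(self):
        g = Grid(2, 5)
        raster = np.zeros((2, 5), dtype=int)
        raster[1, :] = 1
        counties = CountyRaster(g, raster)
        pop = PopulationGrid(g, np.array([[10.0, 20.0, 30.0, 0.0, 40.0],
                                          [1.0, 1.0, 1.0, 1.0, 1.0]]))
        mort = MortalityTable(pd.DataFrame(
            {"county_id": [0, 1], "daily_deaths": [100.0, 5.0]}))
        base = downscale_mortality(mort, counties, pop)
        np.testing.assert_allclose(base.m_cell[0], [10.0, 20.0, 30.0, 0.0, 40.0])
        np.testing.assert_allclose(base.m_cell[1], 1.0)

    def test_single_cell_county_and_uniform_split(self):
        g = Grid(2, 2)
        counties = CountyRaster(g, np.array([[0, 1], [1, 1]]))
        pop = PopulationGrid(g, np.array([[5.0, 2.0], [2.0, 2.0]]))
        mort = MortalityTable(pd.DataFrame(
            {"county_id": [0, 1], "daily_deaths": [7.0, 9.0]}))
        base = downscale_mortality(mort, counties, pop)
        assert base.m_cell[0, 0] == 7.0  # point-mass county
        np.testing.assert_allclose(base.m_cell[counties.county_id == 1], 3.0)

    def test_exact_conservation_on_scene(self, small_scene):
        base = downscale_mortality(small_scene.mortality, small_scene.counties,
                                   small_scene.population)
        for cid, deaths in small_scene.mortality.deaths_by_county().items():
            cell_sum = base.m_cell[small_scene.counties.county_id == cid].sum()
            assert cell_sum == pytest.approx(deaths, rel=1e-9)

    def test_deaths_without_population_rejected(self):
        g = Grid(2, 2)
        counties = CountyRaster(g, np.array([[0, 0], [1, 1]]))
        pop = PopulationGrid(g, np.array([[0.0, 0.0], [1.0, 1.0]]))
        mort = MortalityTable(pd.DataFrame(
            {"county_id": [0, 1], "daily_deaths": [5.0, 5.0]}))
        with pytest.raises(ValidationError):
            downscale_mortality(mort, counties, pop)


class TestExposureHistogram:
    def test_below_floor_all_zero(self):
        hist = exposure_histogram(stack_of(np.full((3, 2, 2), 4.9)), RiskFunction())
        assert hist.counts.sum() == 0

    def test_binning_with_cap(self):
        risk = RiskFunction()
        vals = np.zeros((3, 2, 2))
        vals[:, 0, 0] = [10.2, 10.7, 300.0]
        hist = exposure_histogram(stack_of(vals), risk)
        assert hist.counts[0, 0, 5] == 2          # floor(10.x - 5) = 5
        assert hist.counts[0, 0, hist.n - 1] == 1  # capped into top interval
        assert hist.counts.sum() == 3
        # capped concentration sums are retained per interval
        assert hist.csum[0, 0, 5] == pytest.approx(10.2 + 10.7)
        assert hist.csum[0, 0, hist.n - 1] == pytest.approx(200.0)

    def test_floor_boundary_inclusive(self):
        hist = exposure_histogram(stack_of(np.full((3, 2, 2), 5.0)), RiskFunction())
        assert (hist.counts[:, :, 0] == 3).all()
        assert hist.counts[:, :, 1:].sum() == 0

    def test_counts_bounded_by_days(self, small_scene):
        hist = exposure_histogram(small_scene.truth, RiskFunction())
        assert hist.counts.sum(axis=-1).max() <= small_scene.truth.n_days


class TestRelativeRisk:
    def test_null_slope(self):
        risk = RiskFunction(beta=0.0, beta_high=0.0)
        assert relative_risk(np.array([5.0, 100.0, 200.0]), risk).tolist() == [1.0] * 3

    def test_slope_hand_value(self):
        assert relative_risk(100.0, RiskFunction()) == pytest.approx(1.11)

    def test_linear_log_linear_agree_at_low_dose(self):
        risk_lin = RiskFunction(form="linear")
        risk_log = RiskFunction(form="log_linear")
        c = np.linspace(5.0, 200.0, 40)  # beta*c <= 0.22
        rel = np.abs(relative_risk(c, risk_log) / relative_risk(c, risk_lin) - 1.0)
        assert rel.max() < 0.025

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            RiskFunction(beta_low=0.002, beta=0.001)
        with pytest.raises(ValidationError):
            RiskFunction(c_min=300.0)


class TestAttributableMortality:
    def _one_cell(self, concentrations, m=10.0):
        g = Grid(2, 2)
        vals = np.zeros((len(concentrations), 2, 2))
        vals[:, 0, 0] = concentrations
        m_cell = np.zeros((2, 2))
        m_cell[0, 0] = m
        return stack_of(vals, g), GriddedMortalityBaseline(g, m_cell)

    def test_below_floor_gives_zero_with_zero_ci(self):
        field, base = self._one_cell([4.9])
        res = attributable_mortality(exposure_histogram(field, RiskFunction()),
                                     base, RiskFunction())
        assert (res.total, res.ci_low, res.ci_high) == (0.0, 0.0, 0.0)

    def test_single_day_hand_value(self):
        # C=100 for one day, M=10: 10 * (1.11 - 1) = 1.1; CI from slope bounds
        risk = RiskFunction()
        field, base = self._one_cell([100.0])
        res = attributable_mortality(exposure_histogram(field, risk), base, risk)
        assert res.total == pytest.approx(1.1, rel=1e-9)
        assert res.ci_low == pytest.approx(0.0, abs=1e-12)
        assert res.ci_high == pytest.approx(2.6, rel=1e-9)

    def test_capping_hand_value(self):
        # C=300 capped to 200: 10 * 0.0011 * 200 = 2.2
        risk = RiskFunction()
        field, base = self._one_cell([300.0])
        res = attributable_mortality(exposure_histogram(field, risk), base, risk)
        assert res.total == pytest.approx(2.2, rel=1e-9)

    def test_matches_brute_force_on_random_fields(self):
        rng = np.random.default_rng(31)
        risk = RiskFunction()
        g = Grid(4, 4)
        for _ in range(5):
            vals = rng.uniform(0.0, 250.0, size=(3, 4, 4))
            m_cell = rng.uniform(0.0, 5.0, size=(4, 4))
            base = GriddedMortalityBaseline(g, m_cell)
            res = attributable_mortality(
                exposure_histogram(stack_of(vals, g), risk), base, risk)
            expected = brute_force_deaths(vals, m_cell, risk)
            assert res.total == pytest.approx(expected, rel=1e-9)

    def test_county_rollup_sums_to_total(self, small_scene):
        risk = RiskFunction()
        base = downscale_mortality(small_scene.mortality, small_scene.counties,
                                   small_scene.population)
        res = attributable_mortality(
            exposure_histogram(small_scene.truth, risk), base, risk,
            counties=small_scene.counties)
        assert res.per_county["deaths"].sum() == pytest.approx(res.total, rel=1e-12)
        assert res.per_cell.sum() == pytest.approx(res.total, rel=1e-12)
        assert res.ci_low <= res.total <= res.ci_high
        ok = (res.per_county["ci_low"] <= res.per_county["deaths"] + 1e-12) & (
            res.per_county["deaths"] <= res.per_county["ci_high"] + 1e-12)
        assert ok.all()

    def test_monotonicity_in_beta_concentration_and_mortality(self):
        """Across 100 randomized configurations, deaths never decrease when
        the slope, every concentration, or the baseline mortality grows."""
        rng = np.random.default_rng(77)
        g = Grid(3, 3)
        for _ in range(100):
            vals = rng.uniform(0.0, 220.0, size=(2, 3, 3))
            m_cell = rng.uniform(0.0, 4.0, size=(3, 3))
            beta = rng.uniform(0.0002, 0.002)
            risk = RiskFunction(beta=beta, beta_high=max(beta, 0.0026))
            base = GriddedMortalityBaseline(g, m_cell)

            def deaths(v, m, rk):
                return attributable_mortality(
                    exposure_histogram(stack_of(v, g), rk),
                    GriddedMortalityBaseline(g, m), rk).total

            d0 = deaths(vals, m_cell, risk)
            risk_up = RiskFunction(beta=beta * 1.5,
                                   beta_high=max(beta * 1.5, 0.0026))
            assert deaths(vals, m_cell, risk_up) >= d0 - 1e-12
            assert deaths(vals + rng.uniform(0.0, 10.0), m_cell, risk) >= d0 - 1e-12
            assert deaths(vals, m_cell * 1.7, risk) >= d0 - 1e-12

    def test_midpoint_representative_close_to_exact(self):
        rng = np.random.default_rng(13)
        risk = RiskFunction()
        g = Grid(3, 3)
        vals = rng.uniform(5.0, 150.0, size=(3, 3, 3))
        base = GriddedMortalityBaseline(g, np.ones((3, 3)))
        hist = exposure_histogram(stack_of(vals, g), risk)
        exact = attributable_mortality(hist, base, risk).total
        mid = attributable_mortality(hist, base, risk,
                                     representative="midpoint").total
        assert mid == pytest.approx(exact, rel=0.02)  # <= 0.5 ug/m3 bin error


class TestSourceAttribution:
    def _setup(self, fused_vals, ctrl_vals, pop_vals=None):
        g = Grid(2, 2)
        fused = stack_of(fused_vals, g)
        ctrl = stack_of(ctrl_vals, g)
        pop = PopulationGrid(g, pop_vals if pop_vals is not None else np.ones((2, 2)))
        base = GriddedMortalityBaseline(g, np.full((2, 2), 2.0))
        return fused, ctrl, base, pop

    def test_no_fire_identity(self):
        vals = np.full((2, 2, 2), 8.0)
        fused, ctrl, base, pop = self._setup(vals, vals)
        rep = source_attribution(fused, ctrl, base, RiskFunction(), pop)
        assert rep.fire_conc_share_pct == 0.0
        assert rep.fire_mortality_share_pct == pytest.approx(0.0)

    def test_all_fire_limit(self):
        fused_vals = np.full((2, 2, 2), 8.0)
        fused, ctrl, base, pop = self._setup(fused_vals, np.zeros((2, 2, 2)))
        rep = source_attribution(fused, ctrl, base, RiskFunction(), pop)
        assert rep.fire_conc_share_pct == pytest.approx(100.0)
        assert rep.fire_mortality_share_pct == pytest.approx(100.0)

    def test_zero_fused_field_rejected(self):
        fused, ctrl, base, pop = self._setup(np.zeros((1, 2, 2)), np.zeros((1, 2, 2)))
        with pytest.raises(UndefinedMetricError):
            source_attribution(fused, ctrl, base, RiskFunction(), pop)

    def test_threshold_amplification(self):
        """Control below the 5 ug/m3 floor over populated cells: the fire
        share of mortality strictly exceeds the fire share of exposure."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            ctrl_vals = rng.uniform(1.0, 4.9, size=(3, 2, 2))
            fused_vals = ctrl_vals + rng.uniform(3.0, 40.0, size=(3, 2, 2))
            fused, ctrl, base, pop = self._setup(fused_vals, ctrl_vals)
            rep = source_attribution(fused, ctrl, base, RiskFunction(), pop)
            assert rep.fire_mortality_share_pct > rep.fire_conc_share_pct

    def test_floored_negative_fire_contribution(self):
        fused_vals = np.full((1, 2, 2), 6.0)
        ctrl_vals = np.full((1, 2, 2), 6.0)
        ctrl_vals[0, 0, 0] = 9.0  # correction dips below the non-fire field
        fused, ctrl, base, pop = self._setup(fused_vals, ctrl_vals)
        rep = source_attribution(fused, ctrl, base, RiskFunction(), pop)
        assert rep.n_floored_cells == 1
        assert rep.popwt_fire >= 0.0
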