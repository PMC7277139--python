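"""Dispersion physics: sigmas, kernel, deposition, decay, mass balance."""

import math

import numpy as np
import pytest

from chemrisk import (
    AccidentScenario,
    BENZYL_CHLORIDE,
    ChemicalProperties,
    GridSpec,
    Puff,
    SoilParameters,
    concentration_field,
    decay_soil_day,
    deposit_hour,
    make_fixture,
    pg_sigmas,
    run_simulation,
    step_hour,
)

CALM_D = {"wind_speed": 0.0, "wind_direction": 0.0, "stability_class": "D"}


class TestPgSigmas:
    def test_unstable_spreads_more_than_stable(self):
        assert pg_sigmas("A", 1000.0)[0] > pg_sigmas("F", 1000.0)[0]
        assert pg_sigmas("A", 1000.0)[1] > pg_sigmas("F", 1000.0)[1]

    def test_monotone_in_distance(self):
        for cls in "ABCDEF":
            y1, z1 = pg_sigmas(cls, 1000.0)
            y2, z2 = pg_sigmas(cls, 2000.0)
            assert y2 > y1 > 0
            assert z2 > z1 > 0

    def test_matches_power_law_by_hand(self):
        # class D at 1 km: 0.08*1000/sqrt(1 + 1e-4*1000), 0.06*1000/sqrt(1 + 1.5e-3*1000)
        sy, sz = pg_sigmas("D", 1000.0)
        assert sy == pytest.approx(80.0 / math.sqrt(1.1), rel=1e-12)
        assert sz == pytest.approx(60.0 / math.sqrt(2.5), rel=1e-12)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="stability"):
            pg_sigmas("G", 1000.0)
        with pytest.raises(ValueError):
            pg_sigmas("D", 0.0)


class TestKernel:
    def test_single_puff_matches_closed_form(self):
        grid = GridSpec(nx=5, ny=5, dx=100.0, dy=100.0, mixing_height=10.0)
        puff = Puff(mass=2.0, x=250.0, y=250.0, sigma_y=80.0)
        field = concentration_field([puff], grid)
        xc, yc = grid.x_centres(), grid.y_centres()
        for j in range(5):
            for i in range(5):
                r2 = (xc[i] - 250.0) ** 2 + (yc[j] - 250.0) ** 2
                expected = (
                    2.0e6 * math.exp(-r2 / (2 * 80.0**2))
                    / (2 * math.pi * 80.0**2 * 10.0)
                )
                assert field[j, i] == pytest.approx(expected, rel=1e-9)

    def test_zero_wind_field_is_radially_symmetric(self):
        grid = GridSpec(nx=11, ny=11, source_cell=(5, 5))
        x0, y0 = grid.source_xy()
        puffs = [Puff(mass=1.0, x=x0, y=y0, sigma_y=grid.dx / 2)]
        chem = ChemicalProperties(name="inert", molecular_weight=100.0)
        puffs, field, _ = step_hour(puffs, CALM_D, chem, grid)
        np.testing.assert_allclose(field, field[::-1], rtol=1e-12)
        np.testing.assert_allclose(field, field[:, ::-1], rtol=1e-12)
        np.testing.assert_allclose(field, field.T, rtol=1e-12)

    def test_zero_wind_zero_decay_conserves_airborne_mass(self):
        grid = GridSpec(nx=11, ny=11, source_cell=(5, 5))
        x0, y0 = grid.source_xy()
        chem = ChemicalProperties(name="inert", molecular_weight=100.0)
        puffs = [Puff(mass=3.0, x=x0, y=y0, sigma_y=50.0)]
        for _ in range(10):
            puffs, _, diag = step_hour(puffs, CALM_D, chem, grid)
            assert diag["exported_kg"] == 0.0
        assert sum(p.mass for p in puffs) == pytest.approx(3.0, rel=1e-9)

    def test_advection_moves_argmax_downwind(self):
        # wind FROM 315 (north-west): the plume must land south-east of the source
        grid = GridSpec(nx=60, ny=60, source_cell=(10, 50))
        x0, y0 = grid.source_xy()
        chem = ChemicalProperties(name="inert", molecular_weight=100.0)
        record = {"wind_speed": 1.0, "wind_direction": 315.0, "stability_class": "D"}
        puffs = [Puff(mass=1.0, x=x0, y=y0, sigma_y=50.0)]
        _, field, _ = step_hour(puffs, record, chem, grid)
        j, i = np.unravel_index(field.argmax(), field.shape)
        assert i > 10 and j < 50


class TestDeposition:
    def test_zero_air_leaves_soil_unchanged(self):
        soil = np.full((3, 3), 7.0)
        out = deposit_hour(np.zeros((3, 3)), BENZYL_CHLORIDE, SoilParameters(), soil)
        np.testing.assert_array_equal(out, soil)

    def test_constant_concentration_increment_by_hand(self):
        # v_d*C*dt / (rho*d) = 0.005 * 3 * 3600 / (1300 * 0.01)
        air = np.zeros((2, 2))
        air[1, 1] = 3.0
        out = deposit_hour(air, BENZYL_CHLORIDE, SoilParameters(), np.zeros((2, 2)))
        assert out[1, 1] == pytest.approx(0.005 * 3.0 * 3600.0 / 13.0, rel=1e-12)
        assert out[0, 0] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deposit_hour(np.zeros((2, 2)), BENZYL_CHLORIDE, SoilParameters(),
                         np.zeros((3, 3)))

    def test_soil_series_monotone_without_soil_decay(self):
        scenario, meteo = make_fixture(seed=0)
        chem = ChemicalProperties(
            name="persistent", molecular_weight=126.58, soil_decay_rate=0.0,
            deposition_velocity=0.005,
        )
        scenario = AccidentScenario(
            chemical=chem, release_mass=scenario.release_mass,
            release_duration=scenario.release_duration,
            start_time=scenario.start_time, grid=scenario.grid,
            horizon_days=scenario.horizon_days,
        )
        history = run_simulation(scenario, meteo)
        assert (np.diff(history.soil_daily, axis=0) >= -1e-15).all()


class TestSoilDecay:
    def test_zero_rate_is_identity(self):
        chem = ChemicalProperties(name="x", molecular_weight=100.0, soil_decay_rate=0.0)
        soil = np.random.default_rng(0).random((4, 4))
        np.testing.assert_array_equal(decay_soil_day(soil, chem), soil)

    def test_ln2_rate_halves(self):
        chem = ChemicalProperties(
            name="x", molecular_weight=100.0, soil_decay_rate=math.log(2.0)
        )
        soil = np.full((2, 2), 8.0)
        np.testing.assert_allclose(decay_soil_day(soil, chem), 4.0, rtol=1e-12)

    def test_semigroup_ten_days(self):
        chem = ChemicalProperties(name="x", molecular_weight=100.0, soil_decay_rate=0.13)
        soil = np.random.default_rng(1).random((3, 3))
        stepped = soil.copy()
        for _ in range(10):
            stepped = decay_soil_day(stepped, chem)
        np.testing.assert_allclose(stepped, soil * math.exp(-1.3), rtol=1e-12)


class TestRunSimulation:
    def test_zero_release_gives_zero_history(self):
        scenario, meteo = make_fixture(seed=0)
        zero = AccidentScenario(
            chemical=scenario.chemical, release_mass=0.0,
            release_duration=scenario.release_duration,
            start_time=scenario.start_time, grid=scenario.grid,
            horizon_days=scenario.horizon_days,
        )
        history = run_simulation(zero, meteo)
        assert not history.air_daily.any()
        assert not history.soil_daily.any()

    def test_linearity_in_release_mass(self, fixture_run):
        scenario, meteo, history = fixture_run
        doubled = AccidentScenario(
            chemical=scenario.chemical, release_mass=2 * scenario.release_mass,
            release_duration=scenario.release_duration,
            start_time=scenario.start_time, grid=scenario.grid,
            horizon_days=scenario.horizon_days,
        )
        h2 = run_simulation(doubled, meteo)
        np.testing.assert_allclose(h2.air_daily, 2 * history.air_daily, rtol=1e-9)
        np.testing.assert_allclose(h2.soil_daily, 2 * history.soil_daily, rtol=1e-9)

    def test_deterministic_given_inputs(self, fixture_run):
        scenario, meteo, history = fixture_run
        again = run_simulation(scenario, meteo)
        np.testing.assert_array_equal(again.air_daily, history.air_daily)
        np.testing.assert_array_equal(again.soil_daily, history.soil_daily)

    def test_short_meteo_rejected_before_computation(self):
        scenario, meteo = make_fixture(seed=0)
        from chemrisk import MeteoSeries

        short = MeteoSeries(meteo.df.iloc[: scenario.horizon_days * 24 - 1])
        with pytest.raises(ValueError, match="horizon"):
            run_simulation(scenario, short)

    def test_mass_ledger_closes(self, fixture_run):
        _, _, history = fixture_run
        assert history.ledger.max_closure_error < 0.01
        assert history.ledger.released == pytest.approx(5000.0, rel=1e-9)

    def test_fields_non_negative(self, fixture_run):
        _, _, history = fixture_run
        assert (history.air_daily >= 0).all()
        assert (history.soil_daily >= 0).all()

    def test_soil_max_declines_after_plume_leaves(self, fixture_run):
        # deposition is over within day 1; decay then shrinks every cell daily
        _, _, history = fixture_run
        smax = history.daily_soil_max()
        assert (np.diff(smax[1:]) < 0).all()

    def test_early_soil_max_near_source(self, fixture_run):
        scenario, _, history = fixture_run
        j, i = np.unravel_index(history.soil_daily[0].argmax(),
                                history.soil_daily[0].shape)
        i0, j0 = scenario.grid.source_cell
        assert abs(i - i0) <= 6 and abs(j - j0) <= 6
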