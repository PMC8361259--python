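"""Conveyor-belt forward model: oracles, invariants, fitting."""

import dataclasses

import numpy as np
import pytest

from pulsechase import conveyor as cv


@pytest.fixture(scope="module")
def eos_blood(grid, avail):
    return cv.simulate_blood_curve(cv.EOSINOPHIL_DEFAULTS, avail, grid)


class TestLabelAvailability:
    def test_rectangular_window(self, grid):
        a = cv.LabelAvailability(amplitude=0.05, window_start=0.0, window_length=0.42)
        u = cv.label_availability_curve(a, grid)
        t = grid.times
        assert u[np.searchsorted(t, 0.2)] == 0.05
        assert u[np.searchsorted(t, 1.0)] == 0.0

    def test_zero_amplitude_is_identically_zero(self, grid):
        u = cv.label_availability_curve(cv.LabelAvailability(amplitude=0.0), grid)
        assert np.all(u == 0)

    def test_rectangle_rule_integral(self, grid):
        a = cv.LabelAvailability(amplitude=0.05)
        u = cv.label_availability_curve(a, grid)
        integral = float(np.sum(u) * grid.dt)
        assert abs(integral - a.amplitude * a.window_length) <= grid.dt * a.amplitude


class TestBloodSimulation:
    def test_no_label_no_enrichment(self, grid):
        curve = cv.simulate_blood_curve(
            cv.EOSINOPHIL_DEFAULTS, cv.LabelAvailability(amplitude=0.0), grid
        )
        assert np.all(curve.enrichment == 0)

    def test_enrichment_bounds(self, eos_blood):
        assert np.all(eos_blood.enrichment >= 0)
        assert np.all(eos_blood.enrichment <= 1.0)
        assert np.all(np.isfinite(eos_blood.enrichment))

    def test_closed_form_oracle_in_degenerate_limit(self):
        """Delta-pulse label + near-deterministic delay matches the analytic
        shifted-exponential decay within 1% everywhere after the shift."""
        grid = cv.SimulationGrid(dt=0.02, horizon=30.0)
        params = cv.KineticParameters(
            delay_shift=2.0, delay_mean_extra=1e-3, blood_half_life=2.5
        )
        a = cv.LabelAvailability(amplitude=0.05, window_length=grid.dt)
        sim = cv.simulate_blood_curve(params, a, grid)
        oracle = cv.closed_form_blood_curve(2.0, 2.5, grid)
        mask = grid.times >= 2.0 + 2 * grid.dt
        rel = np.abs(sim.enrichment[mask] - oracle.enrichment[mask]) / oracle.enrichment[mask]
        assert rel.max() <= 0.01

    def test_fifo_shift(self, grid, avail, eos_blood):
        """Increasing the transit shift by d translates the curve by d."""
        d = 2.0
        shifted = cv.simulate_blood_curve(
            dataclasses.replace(cv.EOSINOPHIL_DEFAULTS, delay_shift=3.6 + d),
            avail,
            grid,
        )
        n = int(round(d / grid.dt))
        np.testing.assert_allclose(
            shifted.enrichment[n:], eos_blood.enrichment[:-n], atol=1e-12
        )

    def test_grid_convergence(self, grid, avail, eos_blood):
        fine = cv.simulate_blood_curve(
            cv.EOSINOPHIL_DEFAULTS, avail, cv.SimulationGrid(dt=0.05, horizon=60.0)
        )
        fv = fine.enrichment[::2]
        mask = fv > 0
        rel = np.abs(eos_blood.enrichment[mask] - fv[mask]) / fv[mask]
        assert rel.max() < 0.005

    def test_mass_conservation(self, grid, avail):
        sol = cv.simulate_conveyor(cv.EOSINOPHIL_DEFAULTS, avail, grid)
        assert np.abs(sol.balance_error).max() <= 1e-6

    def test_mass_conservation_with_time_varying_rates(self, grid, avail):
        def ps(t):
            return np.where(np.asarray(t) < 4.0, 1.0, 0.1)

        def hl(t):
            return np.where(np.asarray(t) < 4.0, 2.5, 4.5)

        sol = cv.simulate_conveyor(
            cv.EOSINOPHIL_DEFAULTS, avail, grid,
            production_scale_fn=ps, half_life_fn=hl,
        )
        assert np.abs(sol.balance_error).max() <= 1e-6

    def test_short_horizon_warns_and_returns_zero(self, avail):
        grid = cv.SimulationGrid(dt=0.1, horizon=30.0)
        params = dataclasses.replace(cv.EOSINOPHIL_DEFAULTS, delay_shift=35.0)
        with pytest.warns(UserWarning, match="horizon"):
            curve = cv.simulate_blood_curve(params, avail, grid)
        assert np.all(curve.enrichment == 0)


class TestAirway:
    def test_zero_blood_gives_zero_airway(self, grid):
        blood = cv.simulate_blood_curve(
            cv.EOSINOPHIL_DEFAULTS, cv.LabelAvailability(amplitude=0.0), grid
        )
        air = cv.simulate_airway_curve(cv.EOSINOPHIL_DEFAULTS, blood, grid)
        assert np.all(air.enrichment == 0)

    @pytest.mark.parametrize("pool", [0.01, 0.5, 10.0, 200.0])
    def test_dilution_below_blood_maximum(self, grid, eos_blood, pool):
        params = dataclasses.replace(cv.EOSINOPHIL_DEFAULTS, airway_pool_relative=pool)
        air = cv.simulate_airway_curve(params, eos_blood, grid)
        assert air.enrichment.max() <= eos_blood.enrichment.max()
        if pool >= 0.5:
            assert air.enrichment.max() < 0.95 * eos_blood.enrichment.max()

    def test_vanishing_pool_with_fast_residence_tracks_blood(self, grid, eos_blood):
        params = dataclasses.replace(
            cv.EOSINOPHIL_DEFAULTS,
            airway_pool_relative=1e-6,
            airway_residence_mean=0.05,
        )
        air = cv.simulate_airway_curve(params, eos_blood, grid)
        assert air.enrichment.max() == pytest.approx(
            eos_blood.enrichment.max(), rel=0.01
        )

    def test_default_airway_peak_lower_and_later(self, grid, eos_blood):
        air = cv.simulate_airway_curve(cv.EOSINOPHIL_DEFAULTS, eos_blood, grid)
        assert air.enrichment.max() < eos_blood.enrichment.max()
        t_air = air.time_grid[np.argmax(air.enrichment)]
        t_blood = eos_blood.time_grid[np.argmax(eos_blood.enrichment)]
        assert t_air > t_blood

    def test_grid_mismatch_rejected(self, grid, eos_blood):
        other = cv.SimulationGrid(dt=0.2, horizon=60.0)
        with pytest.raises(ValueError, match="grid"):
            cv.simulate_airway_curve(cv.EOSINOPHIL_DEFAULTS, eos_blood, other)


class TestDetectionDays:
    def test_all_zero_curve(self, grid):
        curve = cv.CompartmentCurve(
            "blood", "eosinophil", grid.times, np.zeros_like(grid.times),
            np.ones_like(grid.times),
        )
        assert cv.detection_days(curve, 0.0005, list(range(1, 61))) == (None, None)

    def test_threshold_boundary_is_inclusive(self, grid):
        e = np.zeros_like(grid.times)
        e[np.searchsorted(grid.times, 5.0)] = 0.0005
        curve = cv.CompartmentCurve(
            "blood", "eosinophil", grid.times, e, np.ones_like(grid.times)
        )
        assert cv.detection_days(curve, 0.0005, list(range(1, 61))) == (5, 5)

    def test_empty_sampling_days_rejected(self, grid):
        curve = cv.CompartmentCurve(
            "blood", "eosinophil", grid.times, np.zeros_like(grid.times),
            np.ones_like(grid.times),
        )
        with pytest.raises(ValueError, match="nonempty"):
            cv.detection_days(curve, 0.0005, [])


class TestClosedForm:
    def test_zero_before_shift_constant_after_with_long_half_life(self):
        grid = cv.SimulationGrid(dt=0.1, horizon=30.0)
        curve = cv.closed_form_blood_curve(5.0, 1e9, grid)
        before = grid.times < 5.0 - grid.dt / 2
        after = grid.times >= 5.0
        assert np.all(curve.enrichment[before] == 0)
        vals = curve.enrichment[after]
        assert np.allclose(vals, vals[0], rtol=1e-6)


class TestFitKinetics:
    def test_recovers_truth_from_noise_free_observations(self, grid, avail):
        truth = cv.EOSINOPHIL_DEFAULTS
        curve = cv.simulate_blood_curve(truth, avail, grid)
        days = [2, 4, 5, 6, 7, 8, 10, 12, 14, 18, 22, 27, 32]
        obs = [(d, float(curve.at(d))) for d in days]
        init = dataclasses.replace(
            truth, delay_shift=4.5, delay_mean_extra=2.0, blood_half_life=3.4
        )
        res = cv.fit_kinetics(
            obs,
            grid,
            init,
            fixed=(
                "airway_influx_fraction",
                "airway_residence_mean",
                "airway_pool_relative",
                "production_scale",
            ),
            avail=avail,
        )
        for name in ("delay_shift", "delay_mean_extra", "blood_half_life"):
            true_v = getattr(truth, name)
            fit_v = getattr(res.params, name)
            assert abs(fit_v - true_v) / true_v <= 0.15, name

    def test_all_zero_observations_flag_zero_production(self, grid, avail):
        obs = [(d, 0.0) for d in (4, 8, 12, 16)]
        res = cv.fit_kinetics(obs, grid, cv.EOSINOPHIL_DEFAULTS, avail=avail)
        assert res.params.production_scale == 0.0
        assert any("boundary" in f for f in res.flags)

    def test_too_few_points_rejected(self, grid, avail):
        with pytest.raises(ValueError, match="4"):
            cv.fit_kinetics([(4, 0.01), (8, 0.02), (12, 0.01)], grid,
                            cv.EOSINOPHIL_DEFAULTS, avail=avail)


class TestDefaults:
    def test_default_parameter_lookup(self):
        assert cv.default_parameters("eosinophil").blood_half_life == 2.5
        assert cv.default_parameters("basophil").delay_shift == 5.6
        with pytest.raises(ValueError):
            cv.default_parameters("neutrophil")

    def test_packaged_config_matches_code_defaults(self):
        from importlib import resources

        path = resources.files("pulsechase").joinpath("data/default_params.yaml")
        params = cv.read_params_yaml(str(path))
        assert params["eosinophil"] == cv.EOSINOPHIL_DEFAULTS
        assert params["basophil"] == cv.BASOPHIL_DEFAULTS

    def test_params_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "p.yaml"
        cv.write_params_yaml({"eosinophil": cv.EOSINOPHIL_DEFAULTS}, path)
        assert cv.read_params_yaml(path)["eosinophil"] == cv.EOSINOPHIL_DEFAULTS

    def test_curve_csv_columns(self, tmp_path, grid, avail):
        curve = cv.simulate_blood_curve(cv.EOSINOPHIL_DEFAULTS, avail, grid)
        path = tmp_path / "c.csv"
        cv.write_curve_csv(curve, path)
        header = path.read_text().splitlines()[0]
        assert header == "compartment,cell_type,t_days,enrichment,count_relative"

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            cv.KineticParameters(delay_mean_extra=0.0)
        with pytest.raises(ValueError):
            cv.SimulationGrid(dt=0.6)
        with pytest.raises(ValueError):
            cv.SimulationGrid(horizon=10.0)
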