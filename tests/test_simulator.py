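"""Physics engine: ventilation, thermal rules, mass balance, year integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stockiaq.geometry import ArchetypeModel, envelope_area
from stockiaq.simulator import (CO, NO2, PM25, EmissionSource, PollutantSpec,
                                SHELTER_BY_TERRAIN, ThermalParams,
                                VentilationParams, air_change_rate,
                                concentration_step, indoor_temperature_step,
                                simulate_batch, simulate_year, window_state,
                                year_thermal_drivers)
from stockiaq.validation import steady_state_oracle


class TestAirChangeRate:
    def test_no_leakage_no_ventilation(self):
        v = VentilationParams(permeability_q50=1e-9)
        ach = air_change_rate(v, 300.0, 250.0, 4.0, 20.0, 10.0, False)
        assert ach == pytest.approx(0.0, abs=1e-9)

    def test_divide_by_twenty_base(self):
        """q50=10, A=300, V=250 → ach50=12 → base 0.6 h⁻¹ at reference wind."""
        v = VentilationParams(permeability_q50=10.0, shelter_factor=1.0)
        ach = air_change_rate(v, 300.0, 250.0, 4.0, 20.0, 20.0, False)
        assert ach == pytest.approx(0.6)

    def test_city_more_sheltered_than_rural(self):
        args = (300.0, 250.0, 5.0, 20.0, 5.0, False)
        city = air_change_rate(VentilationParams(
            shelter_factor=SHELTER_BY_TERRAIN["city"]), *args)
        rural = air_change_rate(VentilationParams(
            shelter_factor=SHELTER_BY_TERRAIN["rural"]), *args)
        assert city < rural

    def test_window_bonus_added(self):
        v = VentilationParams(permeability_q50=10.0, shelter_factor=1.0)
        closed = air_change_rate(v, 300.0, 250.0, 4.0, 20.0, 20.0, False)
        opened = air_change_rate(v, 300.0, 250.0, 4.0, 20.0, 20.0, True)
        assert opened == pytest.approx(closed + 4.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            air_change_rate(VentilationParams(), 300.0, 0.0, 4.0, 20.0, 10.0, False)


class TestThermalModel:
    def test_equilibrium_unchanged(self):
        th = ThermalParams(internal_gain=0.0)
        assert indoor_temperature_step(15.0, 15.0, th, 1.0, 7, 12.0) == pytest.approx(15.0)

    def test_thermostat_clamp(self):
        """Cold heating-season heating hours hold the setpoint of 22 °C."""
        th = ThermalParams()
        t = indoor_temperature_step(18.0, 0.0, th, 1.0, month=1, hour=17.0)
        assert t == pytest.approx(22.0)

    def test_relaxes_to_outdoor(self):
        th = ThermalParams(internal_gain=0.0)
        t = indoor_temperature_step(30.0, 10.0, th, dt=500.0, month=7, hour=12.0)
        assert t == pytest.approx(10.0, abs=1e-6)


class TestWindowRule:
    @pytest.mark.parametrize("t_in,hour,expected", [
        (24.0, 14.0, True),    # warm daytime
        (22.0, 14.0, False),   # below daytime threshold
        (22.0, 2.0, True),     # above night threshold
        (20.5, 2.0, False),
    ])
    def test_thresholds(self, t_in, hour, expected):
        assert window_state(t_in, hour) is expected

    def test_invalid_hour(self):
        with pytest.raises(ValueError):
            window_state(20.0, np.nan)


class TestConcentrationStep:
    def test_single_backward_euler_step(self):
        """λ=1 h⁻¹, k=0, P=1, C_out=10, C=0, dt=10 min → 10/7 exactly."""
        spec = PollutantSpec("x", 0.0, 1.0, 1.0, timestep_minutes=10)
        c = concentration_step(np.array([0.0]), 10.0, 1.0, np.array([50.0]),
                               spec, mix_rate=0.0)
        assert c[0] == pytest.approx(10.0 / 7.0, rel=1e-12)

    def test_pure_decay_contracts(self):
        spec = PollutantSpec("x", 1e-4, 1.0, 1.0, timestep_minutes=10)
        c = concentration_step(np.array([5.0, 3.0, 1.0, 2.0]), 0.0, 0.7,
                               np.full(4, 25.0), spec)
        assert np.all(c < [5.0, 3.0, 1.0, 2.0]) and np.all(c > 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            concentration_step(np.array([-1.0]), 0.0, 1.0, np.array([50.0]), PM25)

    def test_converges_to_closed_form(self):
        """Held forcing converges to P·λ·C_out/(λ+k), the ODE steady state."""
        lam, P, c_out = 0.5, 0.8, 10.0
        spec = PollutantSpec("x", 0.19 / 3600 / 2.3, P, P, timestep_minutes=10)
        c = np.array([0.0])
        for _ in range(5000):
            c = concentration_step(c, c_out, lam, np.array([50.0]), spec,
                                   mix_rate=0.0)
        assert c[0] == pytest.approx(steady_state_oracle(lam, 0.19, P, c_out),
                                     rel=1e-6)

    @given(st.lists(st.floats(0.0, 100.0), min_size=4, max_size=4),
           st.floats(0.0, 50.0), st.floats(0.01, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_nonnegativity_preserved(self, c0, c_out, lam):
        c = concentration_step(np.array(c0), c_out, lam, np.full(4, 40.0), PM25,
                               active_sources=[(0, 3.0, 0.9, 0.06)])
        assert np.all(c >= 0) and np.all(np.isfinite(c))


@pytest.fixture(scope="module")
def semi():
    return ArchetypeModel("semi", floor_area=90.0, ceiling_height=2.4,
                          terrain="urban")


class TestSimulateYear:
    def test_zero_everything_stays_zero(self, semi, weather):
        res, _ = simulate_year(semi, VentilationParams(), ThermalParams(), PM25,
                               (), weather, 0.0)
        assert np.all(res.zone_concentrations == 0.0)
        assert res.zone_concentrations.shape == (8760, 4)

    def test_conservative_tracer_io_is_one(self, semi, weather):
        """v_d=0, P=1, no sources: indoor converges to outdoor (I/O → 1)."""
        _, metrics = simulate_year(semi, VentilationParams(), ThermalParams(),
                                   CO, (), weather, 10.0, burn_in_hours=168)
        assert metrics.io_ratio[0] == pytest.approx(1.0, abs=1e-3)

    def test_mismatched_series_rejected(self, semi, weather):
        with pytest.raises(ValueError):
            simulate_year(semi, VentilationParams(), ThermalParams(), PM25, (),
                          weather.iloc[:100], 10.0)
        with pytest.raises(ValueError):
            simulate_year(semi, VentilationParams(), ThermalParams(), PM25, (),
                          weather, np.ones(100))

    def test_source_superposition(self, weather, thermal_drivers):
        """With linear dynamics, doubling a source rate doubles its contribution."""
        src = lambda rate: [EmissionSource("living", rate, ((0.0, 24.0),))]
        kw = dict(archetype_id="semi", floor_area=np.array([90.0]),
                  ceiling_height=np.array([2.4]), q50=np.array([11.0]),
                  shelter=np.array([0.85]), spec=CO, weather=weather,
                  c_out=5.0, drivers=thermal_drivers, n_hours=600,
                  record_hourly=True)
        base = simulate_batch(sources=(), **kw)[1].zone_concentrations
        one = simulate_batch(sources=src(3.0), **kw)[1].zone_concentrations
        two = simulate_batch(sources=src(6.0), **kw)[1].zone_concentrations
        np.testing.assert_allclose(two - base, 2 * (one - base),
                                   rtol=1e-6, atol=1e-9)

    def test_timestep_robustness(self, semi, weather):
        """Halving the sub-step changes the annual I/O by far less than 0.5%."""
        spec10 = PollutantSpec("x", 1.04e-4, 1.0, 1.0, timestep_minutes=10)
        spec5 = PollutantSpec("x", 1.04e-4, 1.0, 1.0, timestep_minutes=5)
        _, m10 = simulate_year(semi, VentilationParams(), ThermalParams(),
                               spec10, (), weather, 10.0, burn_in_hours=168)
        _, m5 = simulate_year(semi, VentilationParams(), ThermalParams(),
                              spec5, (), weather, 10.0, burn_in_hours=168)
        assert abs(m10.io_ratio[0] / m5.io_ratio[0] - 1) < 0.005

    def test_io_monotone_in_permeability_and_deposition(self, weather,
                                                        thermal_drivers):
        """Outdoor-pollutant I/O rises with leakage, falls with deposition."""
        kw = dict(archetype_id="semi", floor_area=np.full(3, 90.0),
                  ceiling_height=np.full(3, 2.4),
                  q50=np.array([4.0, 10.0, 20.0]), shelter=np.full(3, 0.85),
                  weather=weather, c_out=10.0, drivers=thermal_drivers,
                  n_hours=2000, burn_in_hours=168)
        io_pm = simulate_batch(spec=PM25, **kw)[0].io_ratio
        io_no2 = simulate_batch(spec=NO2, **kw)[0].io_ratio
        assert np.all(np.diff(io_pm) > 0) and np.all(np.diff(io_no2) > 0)
        assert np.all(io_no2 < io_pm)  # higher deposition loss


class TestArchetypeGeometry:
    def test_zone_volumes_sum_to_dwelling_volume(self):
        m = ArchetypeModel("detached", 120.0, 2.5)
        assert m.zone_volumes.sum() == pytest.approx(120.0 * 2.5, abs=1e-6)

    def test_party_walls_reduce_envelope(self):
        mid = envelope_area("mid_terrace", 90.0, 2.4)
        det = envelope_area("detached", 90.0, 2.4)
        assert mid < det

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError):
            ArchetypeModel("castle", 90.0, 2.4)


def test_heating_only_in_season_and_hours(weather):
    t_in, heating_on, _ = year_thermal_drivers(weather, ThermalParams())
    months = np.repeat(np.arange(1, 13), np.array(
        [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]) * 24)
    hod = np.arange(8760) % 24
    in_hours = ((hod >= 6) & (hod < 8)) | (hod >= 16)
    in_season = np.isin(months, [9, 10, 11, 12, 1, 2, 3, 4, 5])
    assert not heating_on[~(in_hours & in_season)].any()
    assert np.all(t_in[heating_on] >= 22.0 - 1e-9)
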