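"""Desk-scale multizone indoor air pollution simulator.

A lumped replacement for a full building-physics contaminant model: four
zones (kitchen / living / bedroom / rest) exchange air with outdoors at a
dynamically computed air change rate, with each other through a common
mixing node, and lose pollutant to indoor surfaces by deposition. Outdoor
pollutant enters attenuated by an envelope penetration factor; scheduled
indoor sources (heating, cooking, smoking) inject mass, optionally partly
vented at source and optionally with supplemental extract ventilation.

Infiltration uses the engineering divide-by-20 rule on the 50 Pa leakage
rate (ach50 = q50 · envelope area / volume), scaled by a terrain shelter
factor and by a wind/stack superposition term combined in quadrature.
Window opening (temperature-threshold rule) adds a fixed air-change bonus.

Integration is backward Euler at a 5 or 10 minute sub-step (loss terms
implicit, interzonal coupling explicit at the previous sub-step), which is
unconditionally stable and preserves non-negativity for non-negative
forcing. All state updates are vectorised over a batch of dwellings sharing
an archetype, so a year of a few thousand dwellings runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import ARCHETYPES, ZONES, ZONE_VOLUME_FRACTIONS, ArchetypeModel, envelope_area

HOURS_PER_YEAR = 8760
HEATING_MONTHS = frozenset({9, 10, 11, 12, 1, 2, 3, 4, 5})  # September–May
#: mg m⁻³ → ppm for CO at 25 °C, 1 atm: ppm = mg m⁻³ × 24.45 / M
MOLAR_VOLUME_25C = 24.45

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: month (1..12) for each hour of a non-leap year
MONTH_OF_HOUR = np.repeat(np.arange(1, 13), _MONTH_DAYS * 24)

SHELTER_BY_TERRAIN = {"city": 0.7, "urban": 0.85, "rural": 1.0}


@dataclass
class PollutantSpec:
    """Deposition, penetration, unit and time-step conventions for a pollutant."""

    name: str
    deposition_velocity: float        # m s⁻¹
    penetration_heating: float        # envelope penetration, heating season
    penetration_summer: float
    indoor_unit: str = "ug/m3"        # "ug/m3" or "ppm"
    molar_mass: float = 0.0           # g mol⁻¹, for ppm conversion
    timestep_minutes: int = 10

    def __post_init__(self) -> None:
        if self.deposition_velocity < 0:
            raise ValueError("deposition velocity must be >= 0")
        for p in (self.penetration_heating, self.penetration_summer):
            if not 0 <= p <= 1:
                raise ValueError("penetration factor must lie in [0, 1]")
        if self.timestep_minutes not in (5, 10):
            raise ValueError("timestep must be 5 or 10 minutes")

    def deposition_loss(self, surface_to_volume: float = 2.3) -> float:
        """First-order deposition loss rate k = v_d · (S/V), in h⁻¹."""
        return self.deposition_velocity * surface_to_volume * 3600.0


PM25 = PollutantSpec("PM2.5", 2.26e-5, penetration_heating=0.8, penetration_summer=1.0)
NO2 = PollutantSpec("NO2", 1.04e-4, penetration_heating=1.0, penetration_summer=1.0)
CO = PollutantSpec("CO", 0.0, penetration_heating=1.0, penetration_summer=1.0,
                   indoor_unit="ppm", molar_mass=28.01, timestep_minutes=5)


@dataclass
class VentilationParams:
    """Infiltration and window-ventilation parameters for one dwelling (or batch)."""

    permeability_q50: float | np.ndarray = 11.0   # m³ h⁻¹ m⁻² @ 50 Pa
    shelter_factor: float | np.ndarray = 0.85     # terrain wind sheltering, (0, 1]
    window_open_ach_bonus: float = 4.0            # h⁻¹ added while windows open
    stack_coefficient: float = 0.1                # buoyancy term weight, K^-1/2
    wind_reference_speed: float = 4.0             # m s⁻¹

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.permeability_q50) <= 0):
            raise ValueError("q50 must be positive")
        sf = np.asarray(self.shelter_factor)
        if np.any(sf <= 0) or np.any(sf > 1):
            raise ValueError("shelter_factor must lie in (0, 1]")


@dataclass
class ThermalParams:
    """Lumped thermal model and occupant comfort rules."""

    time_constant: float = 20.0          # h, envelope relaxation
    internal_gain: float = 0.15          # °C h⁻¹ equivalent free gains
    thermostat_setpoint: float = 22.0    # °C, September–May
    heating_hours: tuple = ((6.0, 8.0), (16.0, 24.0))
    daytime_open_threshold: float = 23.0  # °C
    night_open_threshold: float = 21.0    # °C
    daytime: tuple = (7.0, 22.0)          # living-room occupancy window

    def __post_init__(self) -> None:
        if self.time_constant <= 0:
            raise ValueError("time_constant must be positive")


@dataclass
class EmissionSource:
    """A scheduled indoor pollutant source.

    ``schedule`` is a list of ``(start_hour, end_hour)`` clock intervals
    (fractional hours, 0–24). ``months`` restricts the schedule to a month
    set (None = all year). ``trigger`` is ``"schedule"`` (active whenever
    scheduled) or ``"thermostat"`` (additionally requires heating demand).
    """

    zone: str
    rate: float | np.ndarray            # mg min⁻¹ while active
    schedule: Sequence[tuple[float, float]]
    months: frozenset | None = None
    vented_fraction: float = 0.0        # removed at source before mixing
    supplemental_ventilation: float = 0.0  # m³ s⁻¹ extract while active
    trigger: str = "schedule"

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.rate) < 0):
            raise ValueError("emission rate must be >= 0")
        if not 0 <= self.vented_fraction <= 1:
            raise ValueError("vented_fraction must lie in [0, 1]")
        for a, b in self.schedule:
            if not (0 <= a <= 24 and 0 <= b <= 24):
                raise ValueError("schedule intervals must lie within 00:00-24:00")
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r}")
        if self.trigger not in ("schedule", "thermostat"):
            raise ValueError(f"unknown trigger {self.trigger!r}")


@dataclass
class SimulationResult:
    """Hourly outputs for one simulated dwelling-year."""

    zone_concentrations: np.ndarray   # (n_hours, n_zones)
    indoor_temperature: np.ndarray    # (n_hours,)
    ach: np.ndarray                   # (n_hours,)
    zone_names: tuple = ZONES


def air_change_rate(vent: VentilationParams, envelope_area, volume, wind_speed,
                    indoor_temp, outdoor_temp, window_open) -> np.ndarray | float:
    """Dwelling air change rate (h⁻¹).

    ach = shelter × (q50·A/V / 20) × sqrt[(u/u_ref)² + s²·|ΔT|] + bonus·open
    """
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("volume must be positive")
    base = np.asarray(vent.permeability_q50) * np.asarray(envelope_area) / volume / 20.0
    wind_term = np.asarray(wind_speed) / vent.wind_reference_speed
    stack_term_sq = vent.stack_coefficient ** 2 * np.abs(
        np.asarray(indoor_temp) - np.asarray(outdoor_temp)
    )
    ach = (np.asarray(vent.shelter_factor) * base
           * np.sqrt(wind_term ** 2 + stack_term_sq)
           + vent.window_open_ach_bonus * np.asarray(window_open, dtype=float))
    return ach


def _in_intervals(t, intervals) -> bool:
    return any(a <= t < b for a, b in intervals)


def indoor_temperature_step(t_in, t_out, thermal: ThermalParams, dt: float,
                            month: int, hour: float):
    """One explicit step of the lumped thermal model.

    First-order relaxation toward outdoor temperature plus free internal
    gains; during September–May heating hours the result is clamped at the
    thermostat setpoint from below.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = np.exp(-dt / thermal.time_constant)
    t_new = t_out + (t_in - t_out) * decay + thermal.internal_gain * dt
    if month in HEATING_MONTHS and _in_intervals(hour % 24, thermal.heating_hours):
        t_new = np.maximum(t_new, thermal.thermostat_setpoint)
    return t_new


def window_state(t_in, hour: float, thermal: ThermalParams = ThermalParams()):
    """Window open/closed from the static comfort thresholds.

    Open iff daytime indoor temperature exceeds the daytime threshold (23 °C)
    or night-time temperature exceeds the night threshold (21 °C). Daytime is
    the living-room occupancy window (07:00–22:00).
    """
    if not 0 <= hour % 24 < 24:
        raise ValueError("hour must lie in [0, 24)")
    day = thermal.daytime[0] <= hour % 24 < thermal.daytime[1]
    threshold = thermal.daytime_open_threshold if day else thermal.night_open_threshold
    return np.asarray(t_in) > threshold if np.ndim(t_in) else t_in > threshold


def concentration_step(C, c_out, ach, zone_volumes, spec: PollutantSpec,
                       active_sources: Iterable[tuple] = (), *,
                       penetration: float | None = None,
                       mix_rate: float = 0.5,
                       surface_to_volume: float = 2.3,
                       dt_minutes: float | None = None):
    """One backward-Euler sub-step of the multizone mass balance.

    Per zone i:  dC_i/dt = P·λ·C_out + β·(C_mix − C_i) − (λ + k + f_i)·C_i
                            + (1 − vented)·E_i / V_i
    with k = v_d·(S/V), β the mixing-node exchange rate, f_i any supplemental
    extract ventilation, and C_mix the volume-weighted dwelling mean at the
    previous sub-step. Loss terms are treated implicitly, so non-negative
    inputs yield non-negative output.

    ``active_sources`` holds tuples
    ``(zone_index, rate_mg_per_min, vented_fraction, supplemental_m3_s)``.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("negative input concentration")
    V = np.asarray(zone_volumes, dtype=float)
    dt = (dt_minutes if dt_minutes is not None else spec.timestep_minutes) / 60.0
    P = spec.penetration_heating if penetration is None else penetration
    k = spec.deposition_loss(surface_to_volume)
    c_mix = (C * V).sum(axis=-1, keepdims=True) / V.sum(axis=-1, keepdims=True)

    src = P * np.asarray(ach)[..., None] * c_out + mix_rate * c_mix
    loss = np.asarray(ach)[..., None] + mix_rate + k + np.zeros_like(C)
    for zi, rate, vented, supp in active_sources:
        src[..., zi] += np.asarray(rate) * 60.0 * (1.0 - vented) / V[..., zi]
        loss[..., zi] += supp * 3600.0 / V[..., zi]
    return (C + dt * src) / (1.0 + dt * loss)


# ---------------------------------------------------------------------------
# year drivers (shared across a batch: weather → indoor temperature, heating
# demand, window state)
# ---------------------------------------------------------------------------

def year_thermal_drivers(weather: pd.DataFrame, thermal: ThermalParams):
    """Hourly indoor temperature, heating-demand flag and window flag.

    Thermal parameters are shared across the stock, so these series are
    computed once per run. Returns ``(t_in, heating_on, window_open)`` each
    of length ``len(weather)``.
    """
    t_out = weather["outdoor_temperature"].to_numpy(dtype=float)
    n = len(t_out)
    months = MONTH_OF_HOUR[np.arange(n) % HOURS_PER_YEAR]
    t_in = np.empty(n)
    heating_on = np.zeros(n, dtype=bool)
    window_open = np.zeros(n, dtype=bool)
    t = float(t_out[0])
    decay = np.exp(-1.0 / thermal.time_constant)
    for h in range(n):
        hod = h % 24
        t = t_out[h] + (t - t_out[h]) * decay + thermal.internal_gain
        if int(months[h]) in HEATING_MONTHS and _in_intervals(hod, thermal.heating_hours):
            if t < thermal.thermostat_setpoint:
                heating_on[h] = True
                t = thermal.thermostat_setpoint
        t_in[h] = t
        window_open[h] = bool(window_state(t, hod, thermal))
    return t_in, heating_on, window_open


def _source_activity(source: EmissionSource, n_hours: int, spd: int,
                     heating_on: np.ndarray) -> np.ndarray:
    """(n_hours, spd) activity mask for one source."""
    hod = np.arange(n_hours) % 24
    months = MONTH_OF_HOUR[np.arange(n_hours) % HOURS_PER_YEAR]
    month_ok = (np.ones(n_hours, dtype=bool) if source.months is None
                else np.isin(months, list(source.months)))
    sub_mid = (np.arange(spd) + 0.5) / spd
    t = hod[:, None] + sub_mid[None, :]          # clock time of each sub-step
    active = np.zeros((n_hours, spd), dtype=bool)
    for a, b in source.schedule:
        active |= (t >= a) & (t < b)
    active &= month_ok[:, None]
    if source.trigger == "thermostat":
        active &= heating_on[:, None]
    return active


@dataclass
class BatchMetrics:
    """Stock-batch simulation outputs (one entry per dwelling)."""

    io_ratio: np.ndarray | None            # occupancy-weighted annual I/O
    max8h: dict = field(default_factory=dict)  # zone -> annual max 8-h rolling mean
    unit: str = "ug/m3"


def simulate_batch(*, archetype_id: str, floor_area: np.ndarray,
                   ceiling_height: np.ndarray, q50: np.ndarray,
                   shelter: np.ndarray, spec: PollutantSpec,
                   weather: pd.DataFrame, c_out: float | np.ndarray,
                   sources: Sequence[EmissionSource] = (),
                   vent: VentilationParams | None = None,
                   thermal: ThermalParams | None = None,
                   mix_rate: float = 0.5, surface_to_volume: float = 2.3,
                   burn_in_hours: int = 0, n_hours: int | None = None,
                   record_hourly: bool = False,
                   drivers: tuple | None = None):
    """Simulate a year for a batch of dwellings of one archetype.

    Source ``rate`` fields may be per-dwelling arrays. Outdoor concentration
    is a scalar or hourly series in the working unit (µg m⁻³, or mg m⁻³ for
    emission-driven CO runs; the 8-h metrics are converted to ppm at output
    when the pollutant is specified in ppm).

    Returns ``(BatchMetrics, SimulationResult | None)`` — the latter holds
    full hourly series when ``record_hourly`` (single dwellings / debugging).
    """
    thermal = thermal or ThermalParams()
    vent = vent or VentilationParams()
    floor_area = np.atleast_1d(np.asarray(floor_area, dtype=float))
    ceiling_height = np.atleast_1d(np.asarray(ceiling_height, dtype=float))
    q50 = np.atleast_1d(np.asarray(q50, dtype=float))
    shelter = np.atleast_1d(np.asarray(shelter, dtype=float))
    n = len(floor_area)
    nh = n_hours if n_hours is not None else len(weather)
    if len(weather) < nh:
        raise ValueError("weather series shorter than simulation horizon")
    c_out_series = np.broadcast_to(np.atleast_1d(np.asarray(c_out, dtype=float)), (nh,)) \
        if np.ndim(c_out) else np.full(nh, float(c_out))
    if np.ndim(c_out) and len(np.atleast_1d(c_out)) not in (1, nh):
        raise ValueError("outdoor series length mismatch")

    volume = floor_area * ceiling_height
    env = envelope_area(archetype_id, floor_area, ceiling_height)
    vfrac = np.array([ZONE_VOLUME_FRACTIONS[z] for z in ZONES])
    V = volume[:, None] * vfrac[None, :]                    # (n, 4)
    base = q50 * env / volume / 20.0

    if drivers is None:
        drivers = year_thermal_drivers(weather.iloc[:nh], thermal)
    t_in, heating_on, window_open = (d[:nh] for d in drivers)
    t_out = weather["outdoor_temperature"].to_numpy(dtype=float)[:nh]
    wind = weather["wind_speed"].to_numpy(dtype=float)[:nh]
    factor = np.sqrt((wind / vent.wind_reference_speed) ** 2
                     + vent.stack_coefficient ** 2 * np.abs(t_in - t_out))
    bonus = vent.window_open_ach_bonus * window_open.astype(float)
    months = MONTH_OF_HOUR[np.arange(nh) % HOURS_PER_YEAR]
    pen = np.where(np.isin(months, list(HEATING_MONTHS)),
                   spec.penetration_heating, spec.penetration_summer)

    spd = 60 // spec.timestep_minutes
    dt = spec.timestep_minutes / 60.0
    k = spec.deposition_loss(surface_to_volume)
    beta = mix_rate
    zone_index = {z: i for i, z in enumerate(ZONES)}
    prepped = []
    for s in sources:
        zi = zone_index[s.zone]
        rate = np.broadcast_to(np.asarray(s.rate, dtype=float), (n,))
        inj = rate * 60.0 * (1.0 - s.vented_fraction) / V[:, zi]   # mg m⁻³ h⁻¹
        f_supp = s.supplemental_ventilation * 3600.0 / V[:, zi]    # h⁻¹
        prepped.append((zi, inj, f_supp, _source_activity(s, nh, spd, heating_on)))

    C = np.zeros((n, len(ZONES)))
    occ_sum = np.zeros(n)
    out_sum = 0.0
    occ_hours = 0
    buf = np.zeros((8, n, len(ZONES)))
    rolsum = np.zeros((n, len(ZONES)))
    max8 = np.full((n, len(ZONES)), -np.inf)
    hourly = np.empty((nh, n, len(ZONES))) if record_hourly else None
    ach_series = np.empty(nh) if record_hourly else None

    vsum = V.sum(axis=1)
    for h in range(nh):
        lam = shelter * base * factor[h] + bonus[h]         # (n,)
        inflow = np.repeat((pen[h] * lam * c_out_series[h])[:, None], len(ZONES), axis=1)
        loss0 = np.repeat(lam[:, None], len(ZONES), axis=1) + (beta + k)
        acc = np.zeros_like(C)
        for j in range(spd):
            c_mix = (C * V).sum(axis=1) / vsum
            src = inflow + beta * c_mix[:, None]
            loss = loss0
            extra = None
            for zi, inj, f_supp, active in prepped:
                if active[h, j]:
                    if extra is None:
                        src = src.copy()
                        extra = loss0.copy()
                        loss = extra
                    src[:, zi] += inj
                    extra[:, zi] += f_supp
            C = (C + dt * src) / (1.0 + dt * loss)
            acc += C
        hour_mean = acc / spd
        if record_hourly:
            hourly[h] = hour_mean
            ach_series[h] = lam[0] if n else np.nan

        hod = h % 24
        if h >= burn_in_hours:
            occ_zone = zone_index["living"] if 7 <= hod < 22 else zone_index["bedroom"]
            occ_sum += hour_mean[:, occ_zone]
            out_sum += c_out_series[h]
            occ_hours += 1
        i8 = h % 8
        rolsum += hour_mean - buf[i8]
        buf[i8] = hour_mean
        if h >= 7:
            np.maximum(max8, rolsum / 8.0, out=max8)

    out_mean = out_sum / max(occ_hours, 1)
    io = (occ_sum / max(occ_hours, 1)) / out_mean if out_mean > 0 else None
    to_ppm = MOLAR_VOLUME_25C / spec.molar_mass if spec.indoor_unit == "ppm" else 1.0
    metrics = BatchMetrics(
        io_ratio=io,
        max8h={z: max8[:, i] * to_ppm for i, z in enumerate(ZONES)},
        unit=spec.indoor_unit,
    )
    result = None
    if record_hourly:
        result = SimulationResult(hourly[:, 0, :], t_in.copy(), ach_series)
    return metrics, result


def simulate_year(archetype: ArchetypeModel, vent: VentilationParams,
                  thermal: ThermalParams, spec: PollutantSpec,
                  sources: Sequence[EmissionSource], weather: pd.DataFrame,
                  c_out_series: float | np.ndarray,
                  surface_to_volume: float = 2.3,
                  burn_in_hours: int = 0) -> tuple[SimulationResult, BatchMetrics]:
    """Simulate one dwelling for a full year, recording hourly series."""
    if len(weather) != HOURS_PER_YEAR:
        raise ValueError("weather must cover exactly 8760 hours")
    if np.ndim(c_out_series) and len(np.atleast_1d(c_out_series)) not in (1, HOURS_PER_YEAR):
        raise ValueError("outdoor concentration series length mismatch")
    metrics, result = simulate_batch(
        archetype_id=archetype.archetype_id,
        floor_area=np.array([archetype.floor_area]),
        ceiling_height=np.array([archetype.ceiling_height]),
        q50=np.atleast_1d(np.asarray(vent.permeability_q50, dtype=float)),
        shelter=np.atleast_1d(np.asarray(vent.shelter_factor, dtype=float)),
        spec=spec, weather=weather, c_out=c_out_series, sources=sources,
        vent=vent, thermal=thermal, mix_rate=archetype.mix_rate,
        surface_to_volume=surface_to_volume, burn_in_hours=burn_in_hours,
        record_hourly=True,
    )
    return result, metrics
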