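"""Exposure metrics computed from simulated concentration series.

Two headline metrics: the occupancy-weighted annual indoor/outdoor (I/O)
ratio for outdoor-sourced pollutants (PM2.5, NO2), and the annual maximum
8-hour rolling mean per room for CO, comparable against the WHO 8.1 ppm
8-hour guideline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import SimulationResult

WHO_CO_8H_PPM = 8.1


@dataclass
class OccupancySchedule:
    """Which zone the occupants are in for each clock interval.

    Default time-activity profile: waking hours (07:00–22:00) in the living
    room, night (22:00–07:00) in the primary bedroom. Intervals must
    partition the 24-h day exactly.
    """

    entries: list = field(default_factory=lambda: [
        ("living", (7.0, 22.0)),
        ("bedroom", (22.0, 24.0)),
        ("bedroom", (0.0, 7.0)),
    ])

    def __post_init__(self) -> None:
        total = sum(b - a for _, (a, b) in self.entries)
        if abs(total - 24.0) > 1e-9:
            raise ValueError("occupancy intervals must partition the 24-h day")

    def zone_of_hour(self, hour_of_day: float) -> str:
        h = hour_of_day % 24
        for zone, (a, b) in self.entries:
            if a <= h < b:
                return zone
        raise ValueError(f"no occupancy entry covers hour {hour_of_day}")

    def zone_index_series(self, n_hours: int, zone_names) -> np.ndarray:
        lookup = {z: i for i, z in enumerate(zone_names)}
        per_day = np.array([lookup[self.zone_of_hour(h)] for h in range(24)])
        return per_day[np.arange(n_hours) % 24]


def occupancy_weighted_io(result: SimulationResult, c_out_series,
                          schedule: OccupancySchedule | None = None,
                          burn_in_hours: int = 0) -> float:
    """Annual occupancy-weighted I/O ratio.

    Ratio of the annual mean occupied-zone concentration to the annual mean
    outdoor concentration (means over the same hours, after any burn-in).
    """
    schedule = schedule or OccupancySchedule()
    conc = result.zone_concentrations
    nh = conc.shape[0]
    c_out = np.broadcast_to(np.atleast_1d(np.asarray(c_out_series, dtype=float)), (nh,)) \
        if np.ndim(c_out_series) else np.full(nh, float(c_out_series))
    zi = schedule.zone_index_series(nh, result.zone_names)
    sel = slice(burn_in_hours, None)
    occupied = conc[np.arange(nh), zi][sel]
    out_mean = c_out[sel].mean()
    if out_mean <= 0:
        raise ValueError("outdoor mean concentration must be positive")
    return float(occupied.mean() / out_mean)


def max_rolling_8h_mean(series) -> float:
    """Maximum over all contiguous 8-hour windows of the window mean."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("series must be 1-D with length >= 8")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    windows = (csum[8:] - csum[:-8]) / 8.0
    return float(windows.max())


def deposition_velocity_from_rate(rate: float, surface_to_volume: float) -> float:
    """Convert a first-order deposition rate (h⁻¹) to a deposition velocity (m s⁻¹).

    v_d = (rate / 3600) / (S/V). The English-stock internal
    surface-to-volume ratio is ≈ 2.3 m⁻¹ (2.335 m⁻¹ unrounded).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if surface_to_volume <= 0:
        raise ValueError("surface_to_volume must be positive")
    return (rate / 3600.0) / surface_to_volume


def exceeds_who(max8h_ppm: float, threshold: float = WHO_CO_8H_PPM) -> bool:
    """True iff the annual max 8-h CO mean strictly exceeds the guideline (8.1 ppm)."""
    if max8h_ppm < 0:
        raise ValueError("max8h must be >= 0")
    return bool(max8h_ppm > threshold)
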