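"""Synthetic inputs: EPC-like dwelling stock, geography, outdoor grids, weather.

This module stands in for the external datasets the exposure analysis needs —
a national Energy Performance Certificate (EPC) style dwelling register, a
rectangular background outdoor-pollution grid (annual-mean PM2.5 and NO2 in
µg m⁻³, annual max 8-h CO in ppm), a postcode → grid-cell → local-authority
geography with per-authority smoking prevalence, and one year of hourly
weather. Everything is generated from explicit seeded random streams so the
whole pipeline is reproducible and testable offline.

Draw order within :func:`generate_stock` is fixed and documented (building
refs, dates, postcodes, categorical fields in declaration order, continuous
fields in declaration order, age band, U-values, mains-gas, duplicates,
missing-field injection) so that adding a field later never perturbs earlier
draws for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import ARCHETYPES, FLAT_ARCHETYPES

MISSING = "NA"  # sentinel used when serialising injected-missing fields

#: Stock composition: fraction of dwellings per category (categorical mix of
#: the English EPC register used as the modelling baseline).
DEFAULT_CATEGORY_PROPORTIONS: dict[str, dict[str, float]] = {
    "archetype": {
        "end_terrace": 0.092,
        "mid_terrace": 0.193,
        "semi": 0.233,
        "detached": 0.140,
        "bungalow": 0.094,
        "converted_flat": 0.235,
        "low_rise_flat": 0.012,
        "high_rise_flat": 0.001,
    },
    "wall_type": {"cavity": 0.662, "solid": 0.338},
    "terrain": {"city": 0.359, "urban": 0.608, "rural": 0.033},
    "main_fuel": {
        "gas": 0.809,
        "kerosene": 0.007,
        "lpg": 0.038,
        "solid": 0.009,
        "electric": 0.137,
    },
    # construction-age mix: stand-in (not part of the published composition)
    "age_band": {"pre1930": 0.35, "1930_1995": 0.45, "post1995": 0.20},
}

#: Continuous dwelling parameters: family + bounds (+ loc/scale). Truncated
#: normals bracket English-stock survey ranges; floor area is lognormal-like.
DEFAULT_CONTINUOUS_PARAMS: dict[str, dict] = {
    "permeability_q50": {  # m³ h⁻¹ m⁻² @ 50 Pa
        "family": "truncnorm", "loc": 11.0, "scale": 5.0, "bounds": (2.0, 30.0),
    },
    "floor_area": {  # m²
        "family": "lognormal", "loc": np.log(85.0), "scale": 0.45, "bounds": (25.0, 350.0),
    },
    "ceiling_height": {  # m
        "family": "truncnorm", "loc": 2.4, "scale": 0.15, "bounds": (2.2, 3.0),
    },
    "glazing_ratio": {  # window / exposed-wall fraction
        "family": "truncnorm", "loc": 0.2, "scale": 0.06, "bounds": (0.1, 0.4),
    },
}

# nominal U-values (W m⁻² K⁻¹) by age band: (wall, roof, window)
_U_BY_AGE = {
    "pre1930": (1.8, 1.5, 4.8),
    "1930_1995": (1.2, 0.6, 3.1),
    "post1995": (0.5, 0.2, 2.0),
}

_OUTDOOR_DEFAULTS = {
    "pm25_annual_mean": {"mean": 11.3, "spread": 1.1, "bounds": (8.6, 14.6), "corr_length": 5},
    "no2_annual_mean": {"mean": 26.0, "spread": 8.0, "bounds": (9.9, 53.7), "corr_length": 4},
    "co_max_8h": {"mean": 0.75, "spread": 0.30, "bounds": (0.2, 1.8), "corr_length": 4},
}

DEFAULT_CLIMATE = {
    "annual_mean_temp": 11.0,   # °C
    "seasonal_amplitude": 7.0,  # °C, warmest around mid-July
    "diurnal_amplitude": 3.0,   # °C, warmest mid-afternoon
    "noise_sd": 1.5,            # °C
    "weibull_shape": 2.0,
    "weibull_scale": 4.5,       # m s⁻¹
}

HOURS_PER_YEAR = 8760  # non-leap year; hour 0 = Jan 1 00:00 local


class ConfigurationError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass
class StockConfig:
    """Configuration for the synthetic dwelling-stock generator."""

    n_dwellings: int = 5000
    seed: int = 0
    category_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CATEGORY_PROPORTIONS.items()}
    )
    continuous_params: Mapping[str, Mapping] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONTINUOUS_PARAMS.items()}
    )
    n_postcodes: int | None = None      # default: ~7 dwellings per postcode
    duplicate_fraction: float = 0.05    # re-inspected buildings (same ref, new date)
    missing_fraction: float = 0.02      # records with a missing required field

    def __post_init__(self) -> None:
        if self.n_dwellings < 0:
            raise ConfigurationError("n_dwellings must be non-negative")
        for fld, props in self.category_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"proportions for {fld!r} sum to {total}, expected 1"
                )
            if any(p < 0 for p in props.values()):
                raise ConfigurationError(f"negative proportion in {fld!r}")
        for name, desc in self.continuous_params.items():
            lo, hi = desc["bounds"]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(f"bounds for {name!r} must be finite and ordered")
        if self.n_postcodes is None:
            self.n_postcodes = max(1, self.n_dwellings // 7)


def _draw_continuous(rng: np.random.Generator, desc: Mapping, n: int) -> np.ndarray:
    lo, hi = desc["bounds"]
    family = desc["family"]
    if family == "truncnorm":
        a = (lo - desc["loc"]) / desc["scale"]
        b = (hi - desc["loc"]) / desc["scale"]
        return stats.truncnorm.rvs(a, b, loc=desc["loc"], scale=desc["scale"],
                                   size=n, random_state=rng)
    if family == "lognormal":
        x = rng.lognormal(desc["loc"], desc["scale"], size=n)
        return np.clip(x, lo, hi)
    if family == "uniform":
        return rng.uniform(lo, hi, size=n)
    raise ConfigurationError(f"unknown distribution family {family!r}")


def generate_stock(config: StockConfig) -> pd.DataFrame:
    """Generate an EPC-like dwelling table.

    Returns one row per certificate record. A configurable fraction of
    building references appear twice with distinct inspection dates, and a
    configurable fraction of records have a required field blanked (NaN in
    memory, the ``NA`` sentinel on disk) — both exist to exercise the
    cleaning stage downstream.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_dwellings
    if n == 0:
        return pd.DataFrame()

    refs = np.array([f"B{i:07d}" for i in range(n)])
    dates = pd.to_datetime("2010-01-01") + pd.to_timedelta(
        rng.integers(0, 3650, size=n), unit="D"
    )
    postcodes = np.array(
        [f"PC{i:06d}" for i in rng.integers(0, config.n_postcodes, size=n)]
    )

    cols: dict = {
        "building_ref": refs,
        "inspection_date": dates.normalize(),
        "postcode": postcodes,
    }
    for fld, props in config.category_proportions.items():
        levels = list(props)
        cols[fld] = rng.choice(levels, size=n, p=[props[k] for k in levels])
    for name, desc in config.continuous_params.items():
        cols[name] = _draw_continuous(rng, desc, n)

    df = pd.DataFrame(cols)

    u_wall, u_roof, u_window = zip(*(_U_BY_AGE[a] for a in df["age_band"]))
    jitter = rng.normal(1.0, 0.08, size=(3, n))
    df["wall_U"] = np.maximum(np.array(u_wall) * jitter[0], 0.25)
    df["roof_U"] = np.maximum(np.array(u_roof) * jitter[1], 0.12)
    df["window_U"] = np.maximum(np.array(u_window) * jitter[2], 1.2)

    gas = df["main_fuel"].to_numpy() == "gas"
    p_mains = np.where(gas, 0.97, 0.15)
    df["mains_gas"] = rng.random(n) < p_mains
    df["retrofitted"] = False

    # duplicate records: same building ref, later inspection date
    n_dup = int(round(config.duplicate_fraction * n))
    if n_dup:
        idx = rng.choice(n, size=n_dup, replace=False)
        dup = df.iloc[idx].copy()
        dup["inspection_date"] = dup["inspection_date"] + pd.to_timedelta(
            rng.integers(90, 2000, size=n_dup), unit="D"
        )
        df = pd.concat([df, dup], ignore_index=True)

    # missing-field injection (floor_area is required downstream)
    n_miss = int(round(config.missing_fraction * len(df)))
    if n_miss:
        idx = rng.choice(len(df), size=n_miss, replace=False)
        which = rng.integers(0, 2, size=n_miss)
        fa = df.columns.get_loc("floor_area")
        q50 = df.columns.get_loc("permeability_q50")
        df.iloc[idx[which == 0], fa] = np.nan
        df.iloc[idx[which == 1], q50] = np.nan

    return df


def generate_geography(
    n_postcodes: int,
    grid_shape: tuple[int, int] = (30, 30),
    n_authorities: int = 30,
    prevalence_range: tuple[float, float] = (0.10, 0.25),
    seed: int = 0,
) -> pd.DataFrame:
    """Postcode → grid-cell → local-authority lookup with smoking prevalence.

    Several postcodes may share one grid cell (needed downstream when
    postcode units are merged before spatial correlation). Every postcode
    maps to exactly one cell and one authority.
    """
    if n_postcodes < 1:
        raise ConfigurationError("n_postcodes must be >= 1")
    nr, nc = grid_shape
    if nr < 1 or nc < 1:
        raise ConfigurationError("grid_shape must be positive")
    lo, hi = prevalence_range
    if not (0 <= lo <= hi <= 1):
        raise ConfigurationError("prevalence_range must lie within [0, 1]")

    rng = np.random.default_rng(seed)
    prevalence = rng.uniform(lo, hi, size=n_authorities)
    authority = rng.integers(0, n_authorities, size=n_postcodes)
    return pd.DataFrame(
        {
            "postcode": [f"PC{i:06d}" for i in range(n_postcodes)],
            "grid_row": rng.integers(0, nr, size=n_postcodes),
            "grid_col": rng.integers(0, nc, size=n_postcodes),
            "local_authority": [f"LA{a:03d}" for a in authority],
            "smoking_prevalence": prevalence[authority],
        }
    )


def generate_outdoor_grid(
    grid_shape: tuple[int, int] = (30, 30),
    field_stats: Mapping[str, Mapping] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rectangular outdoor-pollution grid (one row per cell).

    Each pollutant field is spatially smoothed Gaussian noise rescaled to the
    configured mean/spread and clipped to configured bounds, emulating the
    smooth large-scale gradients of an urban background-pollution surface.
    ``spread=0`` yields a uniform field equal to the mean.
    """
    stats_ = {k: dict(v) for k, v in _OUTDOOR_DEFAULTS.items()}
    if field_stats:
        for k, v in field_stats.items():
            stats_.setdefault(k, {}).update(v)
    rng = np.random.default_rng(seed)
    nr, nc = grid_shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    out = pd.DataFrame({"grid_row": rows.ravel(), "grid_col": cols.ravel()})
    for name, st in stats_.items():
        mean, spread = float(st["mean"]), float(st.get("spread", 0.0))
        if mean < 0:
            raise ConfigurationError(f"negative configured mean for {name!r}")
        if spread == 0:
            vals = np.full(nr * nc, mean)
        else:
            z = rng.normal(size=(nr, nc))
            z = ndimage.uniform_filter(z, size=int(st.get("corr_length", 4)), mode="wrap")
            z = (z - z.mean()) / max(z.std(), 1e-12)
            field_vals = mean + spread * z
            lo, hi = st.get("bounds", (0.0, np.inf))
            vals = np.clip(field_vals, lo, hi).ravel()
        out[name] = np.maximum(vals, 0.0)
    return out


def generate_weather(climate_params: Mapping | None = None, seed: int = 0) -> pd.DataFrame:
    """One non-leap year (8760 h) of outdoor temperature and wind speed.

    Temperature = annual mean + seasonal sinusoid (warmest mid-July)
    + diurnal sinusoid (warmest mid-afternoon) + Gaussian noise.
    Wind speeds are i.i.d. Weibull.
    """
    p = dict(DEFAULT_CLIMATE)
    if climate_params:
        p.update(climate_params)
    if p["weibull_scale"] <= 0:
        raise ConfigurationError("weibull_scale must be positive")
    rng = np.random.default_rng(seed)
    hours = np.arange(HOURS_PER_YEAR)
    day = hours / 24.0
    hod = hours % 24
    temp = (
        p["annual_mean_temp"]
        + p["seasonal_amplitude"] * np.cos(2 * np.pi * (day - 199.0) / 365.0)
        + p["diurnal_amplitude"] * np.cos(2 * np.pi * (hod - 15.0) / 24.0)
        + (rng.normal(0.0, p["noise_sd"], size=HOURS_PER_YEAR) if p["noise_sd"] else 0.0)
    )
    wind = p["weibull_scale"] * rng.weibull(p["weibull_shape"], size=HOURS_PER_YEAR)
    return pd.DataFrame(
        {"hour": hours, "outdoor_temperature": temp, "wind_speed": wind}
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write a generated table as UTF-8 CSV with the explicit NA sentinel."""
    df.to_csv(path, index=False, na_rep=MISSING)
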