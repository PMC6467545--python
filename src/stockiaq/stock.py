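"""Clean and parameterise EPC-like records into metamodel inputs.

Covers record deduplication (latest certificate per building reference),
a simplified permeability scheme standing in for the full UK SAP
parameterisation, the whole-stock retrofit scenario (fabric U-values to
age/fabric minima, airtightening as air-change-rate reductions re-expressed
as 50 Pa permeability), and per-dwelling CO emission configurations for
heating, cooking and smoking sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import FLAT_ARCHETYPES, envelope_area
from .simulator import HEATING_MONTHS, SHELTER_BY_TERRAIN, EmissionSource

#: CO emission rate while heating is active, mg min⁻¹, by main fuel
HEATING_CO_RATES = {
    "gas": 15.9,
    "lpg": 8.7,
    "kerosene": 1.7,   # heating oil
    "solid": 2889.0,   # house coal / wood
    "electric": 0.0,   # community or electric: no combustion on site
}
COOKING_CO_RATE = 29.0          # mg min⁻¹, gas stove
SMOKING_CO_RATE = 7.2           # mg min⁻¹ while a cigarette is lit
HEATING_VENTED_FRACTION = 0.9   # 90% of heating CO vented outside
COOKING_EXTRACT_FAN = 0.06      # m³ s⁻¹ kitchen extract during cooking
HEATING_SCHEDULE = ((6.0, 8.0), (16.0, 24.0))
COOKING_SCHEDULE = ((7.0 + 40.0 / 60.0, 8.0), (19.0, 19.5))
SMOKING_SCHEDULE = tuple((float(h), h + 5.0 / 60.0) for h in range(8, 22))

# accept common display spellings of categorical levels
_ARCHETYPE_ALIASES = {
    "end terrace": "end_terrace", "mid terrace": "mid_terrace", "semi": "semi",
    "detached": "detached", "bungalow": "bungalow",
    "converted flats": "converted_flat", "converted flat": "converted_flat",
    "low rise flats": "low_rise_flat", "low rise flat": "low_rise_flat",
    "high rise flats": "high_rise_flat", "high rise flat": "high_rise_flat",
}
_FUEL_ALIASES = {
    "gas (mains)": "gas", "gas": "gas",
    "bulk lpg": "lpg", "bottled gas - propane": "lpg", "lpg/propane": "lpg",
    "lpg": "lpg",
    "heating oil": "kerosene", "kerosene": "kerosene",
    "house coal, wood or solids": "solid", "solid": "solid",
    "community or electric": "electric", "electric/community": "electric",
    "electric": "electric",
}

#: simplified SAP-like base infiltration by construction age band, h⁻¹
BASE_ACH_BY_AGE = {"pre1930": 1.0, "1930_1995": 0.7, "post1995": 0.5}
ACH_ADDER_SOLID_FUEL_FLUE = 0.1
ACH_ADDER_SUSPENDED_FLOOR = 0.05   # applied to pre-1930 (suspended timber floors)

REQUIRED_FIELDS = ("floor_area", "ceiling_height", "glazing_ratio",
                   "archetype", "terrain", "main_fuel", "age_band")


@dataclass
class RetrofitRule:
    """Whole-stock retrofit: U-value minima and airtightening reductions."""

    wall_u_min: Mapping[str, float] = field(
        default_factory=lambda: {"cavity": 0.35, "solid": 0.30})
    roof_u_min: float = 0.16
    window_u_min: float = 1.4
    ach_reductions: Mapping[str, float] = field(default_factory=lambda: {
        "draught_stripping": 0.10,
        "floor_sealing": 0.05,
        "cavity_insulation": 0.10,
        "solid_wall_insulation": 0.15,
        "loft_insulation": 0.05,
    })
    ach_floor: float = 0.1  # h⁻¹, never airtighten below this

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.ach_reductions.values()):
            raise ValueError("ach reductions must be >= 0")


def canonical_archetype(value: str) -> str:
    key = str(value).strip().lower().replace("_", " ")
    key = _ARCHETYPE_ALIASES.get(key, key.replace(" ", "_"))
    if key not in {a for a in _ARCHETYPE_ALIASES.values()}:
        raise ValueError(f"unmappable archetype: {value!r}")
    return key


def canonical_fuel(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _FUEL_ALIASES:
        raise ValueError(f"unknown fuel: {value!r}")
    return _FUEL_ALIASES[key]


def deduplicate(records: pd.DataFrame, return_log: bool = False):
    """One record per building reference, keeping the latest inspection.

    Records missing a required field are removed first. Ties on inspection
    date are broken deterministically by sorting on all columns, so the
    result is invariant to the input row order.
    """
    df = records.copy()
    n_in = len(df)
    required = [c for c in REQUIRED_FIELDS if c in df.columns]
    complete = df[required].notna().all(axis=1)
    df = df[complete]
    n_missing = n_in - len(df)
    sort_cols = ["building_ref", "inspection_date"] + [
        c for c in df.columns if c not in ("building_ref", "inspection_date")]
    df = df.sort_values(sort_cols, kind="mergesort")
    out = df.groupby("building_ref", as_index=False, sort=True).tail(1)
    out = out.sort_values("building_ref", kind="mergesort").reset_index(drop=True)
    log = {"input": n_in, "removed_missing": int(n_missing),
           "removed_duplicates": int(len(df) - len(out)), "output": len(out)}
    return (out, log) if return_log else out


def _fill_permeability(df: pd.DataFrame) -> pd.Series:
    """Simplified SAP-like permeability for records without a measured q50.

    Base infiltration ach by age band, plus adders for solid-fuel flues and
    (pre-1930) suspended floors, converted to q50 through the divide-by-20
    identity ach = q50 · envelope_area / volume / 20.
    """
    ach = df["age_band"].map(BASE_ACH_BY_AGE).to_numpy(dtype=float)
    ach = ach + np.where(df["main_fuel"].to_numpy() == "solid",
                         ACH_ADDER_SOLID_FUEL_FLUE, 0.0)
    ach = ach + np.where(df["age_band"].to_numpy() == "pre1930",
                         ACH_ADDER_SUSPENDED_FLOOR, 0.0)
    volume = df["floor_area"].to_numpy() * df["ceiling_height"].to_numpy()
    env = np.array([
        envelope_area(a, fa, ch) for a, fa, ch in
        zip(df["archetype"], df["floor_area"], df["ceiling_height"])
    ])
    return pd.Series(ach * 20.0 * volume / env, index=df.index)


def parameterise(records: pd.DataFrame) -> pd.DataFrame:
    """Convert cleaned records into metamodel input rows.

    Archetypes and fuels are mapped to canonical levels, the measured
    permeability is passed through where present (filled by the simplified
    SAP-like scheme otherwise), and derived columns (envelope area, volume,
    natural-infiltration ach estimate, shelter factor) are attached.
    """
    df = records.copy().reset_index(drop=True)
    df["archetype"] = [canonical_archetype(a) for a in df["archetype"]]
    df["main_fuel"] = [canonical_fuel(f) for f in df["main_fuel"]]
    if "permeability_q50" not in df.columns:
        df["permeability_q50"] = np.nan
    missing = df["permeability_q50"].isna()
    if missing.any():
        df.loc[missing, "permeability_q50"] = _fill_permeability(df[missing])
    df["volume"] = df["floor_area"] * df["ceiling_height"]
    df["envelope_area"] = [
        envelope_area(a, fa, ch)
        for a, fa, ch in zip(df["archetype"], df["floor_area"], df["ceiling_height"])
    ]
    df["ach_estimate"] = (df["permeability_q50"] * df["envelope_area"]
                          / df["volume"] / 20.0)
    df["shelter_factor"] = df["terrain"].map(SHELTER_BY_TERRAIN)
    if df["shelter_factor"].isna().any():
        bad = sorted(set(df.loc[df["shelter_factor"].isna(), "terrain"]))
        raise ValueError(f"unknown terrain level(s): {bad!r}")
    if "retrofitted" not in df.columns:
        df["retrofitted"] = False
    return df


def retrofit(records: pd.DataFrame, rules: RetrofitRule | None = None) -> pd.DataFrame:
    """Whole-stock retrofit scenario on a parameterised table.

    Fabric U-values drop to their age/fabric minima; the air change rate is
    reduced by every applicable measure (draught-stripping and floor sealing
    everywhere; cavity or solid-wall insulation by wall type; loft
    insulation for houses), floored at ``rules.ach_floor``; the 50 Pa
    permeability is re-derived from the reduced ach. Records already flagged
    ``retrofitted`` are returned unchanged, making the operation idempotent.
    """
    rules = rules or RetrofitRule()
    df = records.copy()
    todo = ~df["retrofitted"].to_numpy(dtype=bool)
    if not todo.any():
        return df
    sub = df.loc[todo]
    red = rules.ach_reductions
    total = np.full(len(sub), red["draught_stripping"] + red["floor_sealing"])
    total += np.where(sub["wall_type"].to_numpy() == "cavity",
                      red["cavity_insulation"], red["solid_wall_insulation"])
    is_house = ~sub["archetype"].isin(FLAT_ARCHETYPES).to_numpy()
    total += np.where(is_house, red["loft_insulation"], 0.0)
    new_ach = np.maximum(sub["ach_estimate"].to_numpy() - total, rules.ach_floor)
    new_ach = np.minimum(new_ach, sub["ach_estimate"].to_numpy())
    df.loc[todo, "ach_estimate"] = new_ach
    df.loc[todo, "permeability_q50"] = (new_ach * 20.0 * sub["volume"]
                                        / sub["envelope_area"])
    for col, floor in (("roof_U", rules.roof_u_min), ("window_U", rules.window_u_min)):
        if col in df.columns:
            df.loc[todo, col] = np.minimum(sub[col], floor)
    if "wall_U" in df.columns:
        wall_min = sub["wall_type"].map(rules.wall_u_min).to_numpy(dtype=float)
        df.loc[todo, "wall_U"] = np.minimum(sub["wall_U"].to_numpy(), wall_min)
    df.loc[todo, "retrofitted"] = True
    return df


def emission_config(record, smoking: bool) -> list[EmissionSource]:
    """CO emission sources for one dwelling.

    Heating: living room, fuel-specific rate, 90% vented at source,
    06:00–08:00 and 16:00–24:00 September–May, active only under heating
    demand (thermostat trigger). Cooking: kitchen, gas-stove rate iff the
    dwelling has mains gas (electric stove otherwise), with a working
    extract fan. Smoking: living room, 5 minutes per hour 08:00–22:00, no
    supplemental ventilation.
    """
    fuel = canonical_fuel(record["main_fuel"])
    sources = []
    heating_rate = HEATING_CO_RATES[fuel]
    if heating_rate > 0:
        sources.append(EmissionSource(
            zone="living", rate=heating_rate, schedule=HEATING_SCHEDULE,
            months=HEATING_MONTHS, vented_fraction=HEATING_VENTED_FRACTION,
            trigger="thermostat"))
    if bool(record["mains_gas"]):
        sources.append(EmissionSource(
            zone="kitchen", rate=COOKING_CO_RATE, schedule=COOKING_SCHEDULE,
            supplemental_ventilation=COOKING_EXTRACT_FAN))
    if smoking:
        sources.append(EmissionSource(
            zone="living", rate=SMOKING_CO_RATE, schedule=SMOKING_SCHEDULE))
    return sources


def emission_rate_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-dwelling source strengths (metamodel CO inputs)."""
    fuels = [canonical_fuel(f) for f in df["main_fuel"]]
    return pd.DataFrame({
        "heating_rate": [HEATING_CO_RATES[f] for f in fuels],
        "cooking_rate": np.where(df["mains_gas"].to_numpy(dtype=bool),
                                 COOKING_CO_RATE, 0.0),
    }, index=df.index)
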