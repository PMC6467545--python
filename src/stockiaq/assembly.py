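"""Stock-scale exposure assembly and pipeline orchestration.

Joins surrogate outputs to the outdoor-pollution grid, converts I/O ratios
to absolute indoor concentrations, sums indoor- and outdoor-source CO,
weights CO statistics by local-authority smoking prevalence, and produces
the summary statistics of the analysis (weighted median and 1st–99th
percentile interval, WHO-guideline exceedance fraction, postcode-level
indoor–outdoor Pearson correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import design as design_mod
from . import metrics as metrics_mod
from . import simulator as sim
from . import stock as stock_mod
from . import synthetic_data as synth
from .geometry import ARCHETYPES
from .surrogate import Metamodel, predict_metrics, train_metamodel

IO_SCHEMA = ["permeability_q50", "floor_area", "ceiling_height",
             "glazing_ratio", "terrain"]
CO_SCHEMA = IO_SCHEMA + ["heating_rate", "cooking_rate", "smoking"]
#: CO inputs spanning decades enter on a log scale
CO_LOG_FEATURES = ("heating_rate", "floor_area", "permeability_q50")
#: full-batch quasi-Newton training suits the smooth low-dimensional CO
#: response better than SGD with early stopping
CO_HYPERPARAMS = {"solver": "lbfgs", "early_stopping": False,
                  "max_iter": 5000, "hidden_layer_sizes": (128, 64)}


@dataclass
class SummaryStats:
    """Distribution summary: weighted median and 1st–99th percentile interval."""

    median: float
    p1: float
    p99: float
    exceedance: float | None = None
    rho: float | None = None
    n: int = 0


def indoor_from_io(io_ratio, outdoor):
    """Absolute indoor concentration = I/O ratio × outdoor concentration."""
    io_ratio = np.asarray(io_ratio, dtype=float)
    outdoor = np.asarray(outdoor, dtype=float)
    if np.any(io_ratio < 0) or np.any(outdoor < 0):
        raise ValueError("inputs must be non-negative")
    prod = io_ratio * outdoor
    return float(prod) if prod.ndim == 0 else prod


def total_co(indoor_source_max8h, outdoor_max8h):
    """Maximum theoretical 8-h CO: indoor-source + outdoor components.

    An upper bound — the two 8-h windows need not coincide.
    """
    a = np.asarray(indoor_source_max8h, dtype=float)
    b = np.asarray(outdoor_max8h, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("inputs must be non-negative")
    s = a + b
    return float(s) if s.ndim == 0 else s


def smoking_weighted(stat_smoke, stat_nonsmoke, prevalence):
    """Prevalence-weighted mixture p·smoking + (1−p)·non-smoking."""
    p = np.asarray(prevalence, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("prevalence must lie in [0, 1]")
    out = p * np.asarray(stat_smoke, dtype=float) \
        + (1.0 - p) * np.asarray(stat_nonsmoke, dtype=float)
    return float(out) if out.ndim == 0 else out


def weighted_quantile(values, q, weights=None):
    """Weighted interpolated quantile.

    Uses plotting positions p_i = (cumulative weight strictly below i) /
    (total − w_i), which reduce exactly to numpy's linear interpolation when
    all weights are equal.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    if v.size == 1:
        return np.full(np.shape(q), v[0]) if np.ndim(q) else float(v[0])
    below = np.cumsum(w) - w
    denom = w.sum() - w
    denom = np.where(denom <= 0, np.nan, denom)
    p = below / denom
    p[0], p[-1] = 0.0, 1.0
    p = np.fmax.accumulate(np.nan_to_num(p, nan=1.0))
    out = np.interp(q, p, v)
    return float(out) if np.ndim(q) == 0 else out


def summarise(values, weights=None, threshold: float | None = None) -> SummaryStats:
    """Weighted median / 1st / 99th percentiles, plus exceedance fraction.

    ``threshold`` (e.g. the WHO 8.1 ppm 8-h CO guideline) switches on the
    weighted fraction of values strictly above it.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    med, p1, p99 = weighted_quantile(v, [0.5, 0.01, 0.99], w)
    exceed = None
    if threshold is not None:
        exceed = float(np.sum(w * (v > threshold)) / w.sum())
    return SummaryStats(float(med), float(p1), float(p99), exceed, n=int(v.size))


def join_outdoor(stock_df: pd.DataFrame, geography: pd.DataFrame,
                 grid: pd.DataFrame, return_log: bool = False):
    """Attach each dwelling's grid-cell outdoor values via its postcode.

    Dwellings whose postcode is absent from the geography are dropped (and
    counted). Idempotent: re-joining an already joined table replaces the
    same columns.
    """
    if grid.empty:
        raise ValueError("empty outdoor grid")
    df = stock_df.drop(columns=[c for c in grid.columns if c not in
                                ("grid_row", "grid_col")], errors="ignore")
    df = df.drop(columns=["grid_row", "grid_col", "local_authority",
                          "smoking_prevalence"], errors="ignore")
    merged = df.merge(geography, on="postcode", how="left", validate="m:1")
    unmatched = merged["grid_row"].isna()
    merged = merged[~unmatched].merge(grid, on=["grid_row", "grid_col"],
                                      how="left", validate="m:1")
    log = {"input": len(stock_df), "dropped_unmatched": int(unmatched.sum()),
           "output": len(merged)}
    merged = merged.reset_index(drop=True)
    return (merged, log) if return_log else merged


def spatial_correlation(dwelling_table: pd.DataFrame, indoor_col: str,
                        outdoor_col: str) -> tuple[float, int]:
    """Postcode-level indoor–outdoor Pearson correlation.

    Postcode indoor means are dwelling-weighted; postcodes sharing an
    underlying grid cell are merged (again dwelling-weighted) before the
    correlation, removing the duplicated-outdoor-value multicollinearity.
    Returns ``(rho, n_merged_units)``.
    """
    needed = ["postcode", "grid_row", "grid_col", indoor_col, outdoor_col]
    df = dwelling_table[needed]
    cells = df.groupby(["grid_row", "grid_col"]).agg(
        indoor=(indoor_col, "mean"), outdoor=(outdoor_col, "first"))
    if len(cells) < 2:
        raise ValueError("need at least 2 merged spatial units")
    if cells["indoor"].std() == 0 or cells["outdoor"].std() == 0:
        raise ValueError("correlation undefined: zero variance")
    rho = pearsonr(cells["indoor"], cells["outdoor"]).statistic
    return float(rho), int(len(cells))


# ---------------------------------------------------------------------------
# surrogate training workflow
# ---------------------------------------------------------------------------

def _io_space(archetype_id: str) -> design_mod.ParameterSpace:
    terr = synth.DEFAULT_CATEGORY_PROPORTIONS["terrain"]
    return design_mod.ParameterSpace([
        design_mod.ParameterSpec("permeability_q50", "uniform", (0.5, 30.0),
                                 units="m3/h/m2@50Pa"),
        design_mod.ParameterSpec("floor_area", "uniform", (25.0, 350.0), units="m2"),
        design_mod.ParameterSpec("ceiling_height", "uniform", (2.2, 3.0), units="m"),
        design_mod.ParameterSpec("glazing_ratio", "uniform", (0.1, 0.4)),
        design_mod.ParameterSpec("terrain", "categorical",
                                 levels=list(terr), probs=list(terr.values())),
    ])


def _co_space(archetype_id: str) -> design_mod.ParameterSpace:
    space = _io_space(archetype_id)
    space.params.extend([
        design_mod.ParameterSpec("heating_rate", "powerlaw", (0.5, 3000.0),
                                 exponent=1.9, units="mg/min"),
        design_mod.ParameterSpec("cooking_rate", "categorical",
                                 levels=[0.0, stock_mod.COOKING_CO_RATE],
                                 probs=[0.2, 0.8]),
        design_mod.ParameterSpec("smoking", "categorical", levels=[0.0, 1.0],
                                 probs=[0.5, 0.5]),
    ])
    return space


def _co_sources(design: pd.DataFrame) -> list[sim.EmissionSource]:
    cook = design["cooking_rate"].to_numpy(dtype=float)
    return [
        sim.EmissionSource("living", design["heating_rate"].to_numpy(dtype=float),
                           stock_mod.HEATING_SCHEDULE, months=sim.HEATING_MONTHS,
                           vented_fraction=stock_mod.HEATING_VENTED_FRACTION,
                           trigger="thermostat"),
        sim.EmissionSource("kitchen", cook, stock_mod.COOKING_SCHEDULE,
                           supplemental_ventilation=np.where(
                               cook > 0, stock_mod.COOKING_EXTRACT_FAN, 0.0)),
        sim.EmissionSource("living",
                           stock_mod.SMOKING_CO_RATE
                           * design["smoking"].to_numpy(dtype=float),
                           stock_mod.SMOKING_SCHEDULE),
    ]


def _simulate_design(archetype_id: str, design: pd.DataFrame,
                     spec: sim.PollutantSpec, weather: pd.DataFrame,
                     drivers, sources=(), c_out=10.0,
                     surface_to_volume: float = 2.3,
                     n_hours: int | None = None) -> sim.BatchMetrics:
    shelter = design["terrain"].map(sim.SHELTER_BY_TERRAIN).to_numpy(dtype=float)
    metrics, _ = sim.simulate_batch(
        archetype_id=archetype_id,
        floor_area=design["floor_area"].to_numpy(dtype=float),
        ceiling_height=design["ceiling_height"].to_numpy(dtype=float),
        q50=design["permeability_q50"].to_numpy(dtype=float),
        shelter=shelter, spec=spec, weather=weather, c_out=c_out,
        sources=sources, drivers=drivers, burn_in_hours=168,
        surface_to_volume=surface_to_volume, n_hours=n_hours,
    )
    return metrics


def train_surrogates(weather: pd.DataFrame, n_design: int = 2000, seed: int = 0,
                     archetypes=ARCHETYPES, hyperparams: Mapping | None = None,
                     surface_to_volume: float = 2.3, n_hours: int | None = None,
                     ) -> dict[tuple[str, str], Metamodel]:
    """Train all per-archetype metamodels from Latin Hypercube simulator runs.

    Metrics: ``pm25_io``, ``no2_io`` (occupancy-weighted annual I/O) and
    ``co_kitchen`` / ``co_living`` (indoor-source annual max 8-h mean, ppm).
    Returns ``{(archetype, metric): Metamodel}``.
    """
    thermal = sim.ThermalParams()
    drivers = sim.year_thermal_drivers(weather, thermal)
    models: dict[tuple[str, str], Metamodel] = {}
    for ai, arch in enumerate(archetypes):
        dseed = (seed * 97 + ai * 13) % (2**31 - 1)
        io_design = design_mod.latin_hypercube(_io_space(arch), n_design, dseed)
        for pname, spec in (("pm25", sim.PM25), ("no2", sim.NO2)):
            m = _simulate_design(arch, io_design, spec, weather, drivers,
                                 surface_to_volume=surface_to_volume,
                                 n_hours=n_hours)
            models[(arch, f"{pname}_io")] = train_metamodel(
                io_design, m.io_ratio, archetype_id=arch, metric=f"{pname}_io",
                schema=IO_SCHEMA, seed=dseed, clip=(0.0, 1.05),
                hyperparams=hyperparams)
        co_design = design_mod.latin_hypercube(_co_space(arch), n_design, dseed + 1)
        mco = _simulate_design(arch, co_design, sim.CO, weather, drivers,
                               sources=_co_sources(co_design), c_out=0.0,
                               surface_to_volume=surface_to_volume,
                               n_hours=n_hours)
        for room in ("kitchen", "living"):
            models[(arch, f"co_{room}")] = train_metamodel(
                co_design, mco.max8h[room], archetype_id=arch,
                metric=f"co_{room}", schema=CO_SCHEMA, seed=dseed,
                log_target=True, log_features=CO_LOG_FEATURES,
                clip=(0.0, np.inf),
                hyperparams={**CO_HYPERPARAMS, **(hyperparams or {})})
    return models


def apply_surrogates(models: Mapping, stock_df: pd.DataFrame, metric: str,
                     extra_cols: pd.DataFrame | None = None) -> np.ndarray:
    """Predict one metric for every stock row using its archetype's model."""
    rows = stock_df.reset_index(drop=True) if extra_cols is None else pd.concat(
        [stock_df.reset_index(drop=True), extra_cols.reset_index(drop=True)], axis=1)
    out = np.empty(len(rows))
    for arch, sub in rows.groupby("archetype", sort=False):
        model = models[(arch, metric)]
        out[sub.index.to_numpy()] = predict_metrics(model, sub)
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG: dict = {
    "seed": 0,
    "n_dwellings": 5000,
    "grid_shape": (30, 30),
    "n_authorities": 30,
    "prevalence_range": (0.10, 0.25),
    "n_design": 2000,
    "surrogate_hyperparams": None,
    "surface_to_volume": 2.3,
    "surrogate_n_hours": None,
}


def run_pipeline(config: Mapping | None = None, models=None,
                 out_dir: str | Path | None = None) -> dict:
    """Execute the full exposure analysis on synthetic inputs.

    Stages: synthetic inputs → deduplicate/parameterise (current + retrofit
    scenario) → train (or reuse) surrogates → predict I/O and CO metrics →
    join the outdoor grid → smoking-prevalence weighting → summary
    statistics. Returns all tables, summaries and stage logs; optionally
    writes the tables to ``out_dir``.
    """
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    logs: dict = {"seed": seed}

    stock_cfg = synth.StockConfig(n_dwellings=int(cfg["n_dwellings"]), seed=seed)
    raw = synth.generate_stock(stock_cfg)
    geography = synth.generate_geography(
        stock_cfg.n_postcodes, tuple(cfg["grid_shape"]),
        int(cfg["n_authorities"]), tuple(cfg["prevalence_range"]), seed=seed + 1)
    grid = synth.generate_outdoor_grid(tuple(cfg["grid_shape"]), seed=seed + 2)
    weather = synth.generate_weather(seed=seed + 3)

    clean, dedup_log = stock_mod.deduplicate(raw, return_log=True)
    logs["deduplicate"] = dedup_log
    current = stock_mod.parameterise(clean)
    retro = stock_mod.retrofit(current)
    logs["stock_rows"] = len(current)

    if models is None:
        models = train_surrogates(weather, n_design=int(cfg["n_design"]),
                                  seed=seed,
                                  hyperparams=cfg["surrogate_hyperparams"],
                                  surface_to_volume=cfg["surface_to_volume"],
                                  n_hours=cfg["surrogate_n_hours"])
    logs["surrogate_holdout"] = {
        f"{a}/{m}": models[(a, m)].training_summary for (a, m) in models}

    # outdoor join (current and retrofit share geography)
    current, join_log = join_outdoor(current, geography, grid, return_log=True)
    retro = join_outdoor(retro, geography, grid)
    logs["join_outdoor"] = join_log

    exposure = current[["building_ref", "postcode", "archetype",
                        "grid_row", "grid_col", "smoking_prevalence"]].copy()
    summary: dict = {}
    for pname, col in (("pm25", "pm25_annual_mean"), ("no2", "no2_annual_mean")):
        io = apply_surrogates(models, current, f"{pname}_io")
        indoor = indoor_from_io(io, current[col].to_numpy())
        exposure[f"{pname}_io"] = io
        exposure[f"{pname}_outdoor"] = current[col].to_numpy()
        exposure[f"{pname}_indoor"] = indoor
        rho, n_units = spatial_correlation(
            exposure.assign(indoor=indoor), "indoor", f"{pname}_outdoor")
        s_io = summarise(io)
        s_in = summarise(indoor)
        summary[pname] = {
            "io_median": s_io.median, "io_p1": s_io.p1, "io_p99": s_io.p99,
            "indoor_median": s_in.median, "indoor_p1": s_in.p1,
            "indoor_p99": s_in.p99, "rho": rho, "n_spatial_units": n_units,
        }

    # CO: indoor-source metric per scenario × smoking variant + outdoor max 8-h
    co_out = current["co_max_8h"].to_numpy()
    prevalence = current["smoking_prevalence"].to_numpy()
    for scen, table in (("current", current), ("retrofit", retro)):
        rates = stock_mod.emission_rate_columns(table)
        for room in ("kitchen", "living"):
            per_variant = {}
            for smoking in (0.0, 1.0):
                extra = rates.assign(smoking=smoking)
                indoor_src = apply_surrogates(models, table, f"co_{room}", extra)
                per_variant[smoking] = total_co(indoor_src, co_out)
            key = f"co_{room}_{scen}"
            exposure[f"{key}_nonsmoking"] = per_variant[0.0]
            exposure[f"{key}_smoking"] = per_variant[1.0]
            # fractional-weight duplication: each dwelling contributes both
            # variants, weighted by its local-authority smoking prevalence
            values = np.concatenate([per_variant[1.0], per_variant[0.0]])
            weights = np.concatenate([prevalence, 1.0 - prevalence])
            stats = summarise(values, weights, threshold=metrics_mod.WHO_CO_8H_PPM)
            summary[key] = {"median": stats.median, "p1": stats.p1,
                            "p99": stats.p99, "exceedance": stats.exceedance}

    result = {"stock_current": current, "stock_retrofit": retro,
              "exposure": exposure, "summary": summary, "logs": logs,
              "models": models, "geography": geography, "grid": grid,
              "weather": weather}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("stock_current", "stock_retrofit", "exposure"):
            synth.write_table(result[name], out / f"{name}.csv")
        import json
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return result
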