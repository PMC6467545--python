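#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the four external datasets the exposure analysis consumes: an
EPC-like dwelling register (with duplicate certificates and missing fields,
as found in the wild), the postcode → grid-cell → local-authority geography
with smoking prevalence, the outdoor background-pollution grid (PM2.5, NO2
annual means; CO annual max 8-h), and one year of hourly weather. Writes
them under results/inputs/ as plain CSV.
"""

import argparse
from pathlib import Path

from stockiaq import synthetic_data as synth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-dwellings", type=int, default=5000)
    args = ap.parse_args()

    out = ROOT / "results" / "inputs"
    out.mkdir(parents=True, exist_ok=True)

    cfg = synth.StockConfig(n_dwellings=args.n_dwellings, seed=args.seed)
    stock = synth.generate_stock(cfg)
    geography = synth.generate_geography(cfg.n_postcodes, seed=args.seed + 1)
    grid = synth.generate_outdoor_grid(seed=args.seed + 2)
    weather = synth.generate_weather(seed=args.seed + 3)

    for name, df in [("stock_raw", stock), ("geography", geography),
                     ("outdoor_grid", grid), ("weather", weather)]:
        synth.write_table(df, out / f"{name}.csv")

    print(f"stock: {len(stock)} certificate records "
          f"({stock['building_ref'].duplicated().sum()} duplicated refs, "
          f"{stock[['floor_area', 'permeability_q50']].isna().any(axis=1).sum()}"
          " with missing fields)")
    print(f"geography: {len(geography)} postcodes, "
          f"{geography['local_authority'].nunique()} authorities")
    print(f"grid: {len(grid)} cells | NO2 "
          f"{grid['no2_annual_mean'].min():.1f}-{grid['no2_annual_mean'].max():.1f}"
          f" ug/m3, PM2.5 {grid['pm25_annual_mean'].min():.1f}-"
          f"{grid['pm25_annual_mean'].max():.1f} ug/m3")
    print(f"weather: {len(weather)} h, mean "
          f"{weather['outdoor_temperature'].mean():.1f} C")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
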