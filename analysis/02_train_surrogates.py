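#!/usr/bin/env python
"""Train the per-archetype surrogate metamodels.

For each of the eight dwelling archetypes, a 2000-point Latin Hypercube
design over geometry, permeability, terrain (and for CO: power-law heating
emission rate, cooking and smoking sources) is pushed through the multizone
simulator for a full year, and feed-forward networks are fitted to the
resulting metrics (PM2.5 / NO2 occupancy-weighted I/O ratios, CO kitchen
and living-room annual max 8-h means). Model artifacts go to scratch/
(binary); the holdout-quality table goes to results/.
"""

import argparse
import time
from pathlib import Path

import joblib
import pandas as pd

from stockiaq import synthetic_data as synth
from stockiaq.assembly import train_surrogates

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-design", type=int, default=2000)
    args = ap.parse_args()

    weather = synth.generate_weather(seed=args.seed + 3)
    t0 = time.time()
    models = train_surrogates(weather, n_design=args.n_design, seed=args.seed)
    print(f"trained {len(models)} metamodels in {time.time() - t0:.0f} s")

    rows = [{"archetype": a, "metric": m, **models[(a, m)].training_summary}
            for (a, m) in models]
    quality = pd.DataFrame(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    quality.to_csv(out / "surrogate_quality.csv", index=False)

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    joblib.dump(models, scratch / "metamodels.joblib")

    io = quality[quality["metric"].str.endswith("_io")]
    co = quality[~quality["metric"].str.endswith("_io")]
    print(f"I/O models: holdout R2 {io['holdout_r2'].min():.3f}-"
          f"{io['holdout_r2'].max():.3f}, RMSE <= {io['holdout_rmse'].max():.4f}")
    print(f"CO models: log-scale holdout R2 {co['holdout_r2_log'].min():.3f}-"
          f"{co['holdout_r2_log'].max():.3f}")
    print(f"quality table: {out / 'surrogate_quality.csv'}")


if __name__ == "__main__":
    main()
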