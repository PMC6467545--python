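#!/usr/bin/env python
"""Run the stock-scale exposure assembly, current and retrofit scenarios.

Cleans and parameterises the synthetic EPC-like stock, applies the trained
surrogates (reusing scratch/metamodels.joblib when 02 has been run),
joins the outdoor grid, sums indoor- and outdoor-source CO, weights by
local-authority smoking prevalence and writes the per-dwelling exposure
table plus the summary statistics under results/exposure_run/.
"""

import argparse
import json
import time
from pathlib import Path

import joblib

from stockiaq.assembly import run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-dwellings", type=int, default=5000)
    ap.add_argument("--n-design", type=int, default=2000)
    args = ap.parse_args()

    cached = ROOT / "scratch" / "metamodels.joblib"
    models = joblib.load(cached) if cached.exists() else None
    if models is not None:
        print(f"reusing {len(models)} trained metamodels from {cached}")

    t0 = time.time()
    out_dir = ROOT / "results" / "exposure_run"
    res = run_pipeline({"seed": args.seed, "n_dwellings": args.n_dwellings,
                        "n_design": args.n_design}, models=models,
                       out_dir=out_dir)
    print(f"pipeline completed in {time.time() - t0:.0f} s")

    logs = res["logs"]
    print(f"records: {logs['deduplicate']['input']} -> "
          f"{logs['deduplicate']['output']} after cleaning "
          f"({logs['deduplicate']['removed_missing']} missing, "
          f"{logs['deduplicate']['removed_duplicates']} duplicate certificates)")
    print(f"outdoor join: {logs['join_outdoor']['output']} dwellings matched")
    s = res["summary"]
    print(f"PM2.5 I/O median {s['pm25']['io_median']:.2f} "
          f"(p1-p99 {s['pm25']['io_p1']:.2f}-{s['pm25']['io_p99']:.2f}), "
          f"NO2 {s['no2']['io_median']:.2f} "
          f"({s['no2']['io_p1']:.2f}-{s['no2']['io_p99']:.2f})")
    print(json.dumps(s, indent=2)[:400], "...")
    print(f"tables in {out_dir}")


if __name__ == "__main__":
    main()
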