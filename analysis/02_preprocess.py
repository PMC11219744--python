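#!/usr/bin/env python
"""Preprocess the void-level table into analysis-ready samples.

Pools unscheduled voids into the next scheduled sample, substitutes censored
concentrations by LOD/2, adjusts for creatinine and flags samples outside
the 0.3-3.0 g/L creatinine validity range. Writes results/samples.csv and
results/accounting.json.
"""
import argparse
import json
from pathlib import Path

from pahtk.pipeline import RunConfig, stage_preprocess
from pahtk.preprocess import read_table

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=17)
ap.add_argument("--out", default="results")
args = ap.parse_args()

out = Path(args.out)
cfg = RunConfig(seed=args.seed, outdir=str(out))
voids = read_table(out / "voids.csv")
samples, report = stage_preprocess(cfg, voids, out)
print(f"wrote {out/'samples.csv'}")
print(json.dumps(report.to_dict(), indent=2))
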