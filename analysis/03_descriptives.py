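#!/usr/bin/env python
"""Descriptive excretion statistics.

Per-window concentration percentiles, naphthalene-metabolite proportions,
median relative concentration changes (pre-exposure window 2 -> peak
window 4) and Pearson correlations of the log concentrations; also draws the
concentration-time figure.
"""
import argparse
from pathlib import Path

from pahtk.config import ANALYTES, DISPLAY_NAMES
from pahtk.descriptives import relative_change
from pahtk.pipeline import RunConfig, stage_describe
from pahtk.preprocess import read_table

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=17)
ap.add_argument("--out", default="results")
args = ap.parse_args()

out = Path(args.out)
cfg = RunConfig(seed=args.seed, outdir=str(out))
samples = read_table(out / "samples.csv")
described = stage_describe(cfg, samples, out)

print("median relative increase, window 2 -> window 4:")
for name in ANALYTES:
    _, med, skipped = relative_change(samples, name, 2, 4)
    print(f"  {DISPLAY_NAMES[name]}: {med:.1f}-fold ({skipped} sets skipped)")
print("\nmetabolite proportions (% of summed medians):")
print(described["proportions"].to_string(index=False,
                                         float_format=lambda v: f"{v:.1f}"))
print("\ncorrelations of log concentrations:")
print(described["correlations"].to_string(index=False,
                                          float_format=lambda v: f"{v:.3f}"))
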