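#!/usr/bin/env python
"""Assemble the markdown run report from the persisted intermediates, and
project the time needed to return to pre-exposure concentrations from the
fitted DHN kinetics."""
import argparse
import json
from pathlib import Path

from pahtk.kinetics import time_to_baseline
from pahtk.pipeline import RunConfig, stage_report
from pahtk.preprocess import AccountingReport, read_table

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=17)
ap.add_argument("--out", default="results")
args = ap.parse_args()

out = Path(args.out)
cfg = RunConfig(seed=args.seed, outdir=str(out), make_plot=False)
acc = json.loads((out / "accounting.json").read_text())
acc.pop("meta", None)
report = AccountingReport(**acc)
described = {"proportions": read_table(out / "proportions.csv"),
             "correlations": read_table(out / "correlations.csv")}
half_lives = read_table(out / "half_lives.csv")
path = stage_report(cfg, report, described, half_lives, out)
print(f"wrote {path}")

perc = read_table(out / "window_percentiles.csv")
dhn = perc[perc["analyte"] == "DHN"].set_index("window_index")
hl = float(half_lives.set_index("biomarker").loc["DHN", "half_life_h"])
ttb = time_to_baseline(dhn.loc[4, "median"], dhn.loc[2, "median"], hl)
print(f"DHN: median peak {dhn.loc[4,'median']:.1f} µg/g vs baseline "
      f"{dhn.loc[2,'median']:.1f} µg/g -> {ttb.n_halvings:.1f} halvings, "
      f"~{ttb.hours:.0f} h (rounded: {ttb.hours_rounded_n:.0f} h) to baseline")
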