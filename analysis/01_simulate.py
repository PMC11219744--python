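#!/usr/bin/env python
"""Generate the synthetic biomonitoring campaign.

Simulates 6 firefighting instructors x 5 live-fire training sessions with 9
scheduled urine samplings each (plus unscheduled voids) under the packaged
default conditions and writes the void-level table to results/voids.csv.
"""
import argparse
from pathlib import Path

from pahtk.pipeline import RunConfig, stage_simulate

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=17)
ap.add_argument("--out", default="results")
args = ap.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
cfg = RunConfig(seed=args.seed, outdir=str(out))
voids = stage_simulate(cfg, out)
sched = int(voids["scheduled"].sum())
n_sets = cfg.design.n_subjects * cfg.design.n_sessions
print(f"wrote {out/'voids.csv'}: {len(voids)} voids, {sched} scheduled "
      f"({sched // n_sets} per subject-session x {n_sets} sets)")
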