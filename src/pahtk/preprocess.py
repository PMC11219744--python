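"""Void-level data -> analysis-ready creatinine-adjusted samples.

Pipeline: pool unscheduled voids into the next scheduled sample by physical
mixing (volume-weighted concentrations), substitute censored values by LOD/2,
divide by creatinine, and flag samples whose creatinine concentration lies
outside the 0.3-3.0 g/L validity range (bounds inclusive). Excluded samples
are retained with ``included = 0`` so the sample accounting stays auditable.

LOD substitution is applied after pooling, on the pooled measured
concentration, because the assay in the emulated protocol runs on the pooled
physical sample. Substituting before or after creatinine adjustment is
mathematically equivalent for the ratio; this module substitutes first.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalyteConfig

__all__ = [
    "AccountingReport", "pool_voids", "substitute_lod", "adjust_creatinine",
    "apply_inclusion", "process_voids", "write_table", "read_table",
]

CREATININE_BOUNDS = (0.3, 3.0)  # g/L, inclusive


@dataclass
class AccountingReport:
    """Bookkeeping of how many samples survived each gate."""

    expected: int
    collected: int
    included: int
    excluded_creatinine: int
    missing: int

    def __post_init__(self) -> None:
        if self.collected != self.expected - self.missing:
            raise ValueError("collected must equal expected - missing")
        if self.included + self.excluded_creatinine != self.collected:
            raise ValueError("included + excluded must equal collected")

    def to_dict(self) -> dict:
        return asdict(self)


def substitute_lod(measured, below_lod, lod: float):
    """Replace censored values by LOD/2; idempotent, leaves others unchanged."""
    if lod <= 0:
        raise ValueError("lod must be positive")
    measured = np.asarray(measured, dtype=float)
    below = np.asarray(below_lod, dtype=bool)
    out = np.where(below, lod / 2.0, measured)
    return float(out) if out.ndim == 0 else out


def adjust_creatinine(conc, creatinine):
    """ug/L divided by g/L -> ug analyte per g creatinine."""
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        raise ValueError("creatinine concentration must be positive")
    out = np.asarray(conc, dtype=float) / creatinine
    return float(out) if out.ndim == 0 else out


def pool_voids(voids: pd.DataFrame, analytes: Mapping[str, AnalyteConfig]
               ) -> tuple[pd.DataFrame, int]:
    """Pool one subject-session's voids into scheduled samples.

    Every unscheduled void is merged into the *next* scheduled void by mass
    balance: pooled concentration = sum(c_i V_i) / sum(V_i) for analytes and
    creatinine. The below-LOD flag is re-evaluated on the pooled measured
    concentration. Returns (samples, number of trailing unscheduled voids
    dropped because no later scheduled sample exists).
    """
    if len(voids) == 0:
        return voids.iloc[0:0].copy(), 0
    if not voids["scheduled"].astype(bool).any():
        raise ValueError("cannot pool a session without any scheduled void")
    g = voids.sort_values("time_h", kind="mergesort")
    names = list(analytes)
    rows = []
    buf: list = []
    for row in g.itertuples(index=False):
        buf.append(row)
        if not bool(row.scheduled):
            continue
        vols = np.array([r.volume_L for r in buf])
        vtot = vols.sum()
        out = {
            "subject_id": row.subject_id,
            "session_id": row.session_id,
            "window_index": int(row.window_index),
            "time_h": row.time_h,
            "volume_L": vtot,
            "creatinine_g_per_L": float(np.dot(
                [r.creatinine_g_per_L for r in buf], vols) / vtot),
            "n_pooled": len(buf),
        }
        for name in names:
            c = float(np.dot([getattr(r, f"{name}_meas_ug_per_L") for r in buf],
                             vols) / vtot)
            out[f"{name}_ug_per_L"] = c
            out[f"{name}_below_lod"] = int(c < analytes[name].lod)
        rows.append(out)
        buf = []
    trailing = len(buf)
    if trailing:
        warnings.warn(f"dropped {trailing} unscheduled void(s) after the last "
                      "scheduled sample", stacklevel=2)
    return pd.DataFrame(rows), trailing


def apply_inclusion(samples: pd.DataFrame,
                    bounds: tuple[float, float] = CREATININE_BOUNDS,
                    expected: int | None = None
                    ) -> tuple[pd.DataFrame, AccountingReport]:
    """Flag samples by the creatinine validity range and account for totals.

    The bounds are inclusive. ``expected`` defaults to the number of samples
    present (no missing samples).
    """
    lo, hi = bounds
    out = samples.copy()
    ok = (out["creatinine_g_per_L"] >= lo) & (out["creatinine_g_per_L"] <= hi)
    out["included"] = ok.astype(int)
    collected = len(out)
    expected = collected if expected is None else int(expected)
    report = AccountingReport(
        expected=expected,
        collected=collected,
        included=int(ok.sum()),
        excluded_creatinine=int((~ok).sum()),
        missing=expected - collected,
    )
    return out, report


def process_voids(voids: pd.DataFrame, analytes: Mapping[str, AnalyteConfig],
                  bounds: tuple[float, float] = CREATININE_BOUNDS,
                  expected: int | None = None
                  ) -> tuple[pd.DataFrame, AccountingReport]:
    """Full preprocessing: pool, substitute, adjust, flag.

    Besides the anchor sampling time ``time_h`` each sample also carries
    ``t_mid_h``, the midpoint of its collection interval (time span since the
    previous collected sample of the set). Spot concentrations are averages of
    the excretion over that interval, so the midpoint is the natural abscissa
    for elimination kinetics; the anchor time is kept for protocol-style
    reporting and time-to-peak.
    """
    names = list(analytes)
    parts = []
    for _, grp in voids.groupby(["subject_id", "session_id"], sort=True):
        samples, _ = pool_voids(grp, analytes)
        samples = samples.sort_values("time_h", kind="mergesort").reset_index(drop=True)
        prev = samples["time_h"].shift(1)
        t_mid = 0.5 * (samples["time_h"] + prev)
        t_mid.iloc[0] = samples["time_h"].iloc[0]
        samples.insert(4, "t_mid_h", t_mid)
        parts.append(samples)
    pooled = pd.concat(parts, ignore_index=True)
    for name in names:
        sub = substitute_lod(pooled[f"{name}_ug_per_L"],
                             pooled[f"{name}_below_lod"], analytes[name].lod)
        pooled[f"{name}_ug_per_L"] = sub
        pooled[f"{name}_ug_per_g"] = adjust_creatinine(
            sub, pooled["creatinine_g_per_L"])
    return apply_inclusion(pooled, bounds=bounds, expected=expected)


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """CSV writer with an optional leading ``#``-comment metadata line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta is not None:
            fh.write("# meta: " + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
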