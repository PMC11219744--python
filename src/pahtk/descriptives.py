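"""Descriptive layer: per-window percentiles, relative changes, metabolite
proportions and correlations of log concentrations.

Percentiles default to linear interpolation between order statistics
(h = (n-1)p + 1); the weighted-average convention (h = (n+1)p, numpy's
``weibull``) is available because commercial packages differ in the quartile
rule. Medians agree between the two.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult", "summarize_by_window", "relative_change",
    "metabolite_proportions", "log_pearson",
]


@dataclass(frozen=True)
class CorrelationResult:
    analyte_pair: tuple[str, str]
    n: int
    r: float
    p: float


def summarize_by_window(samples: pd.DataFrame, analytes: Sequence[str],
                        method: str = "linear") -> pd.DataFrame:
    """Median/quartiles/range of adjusted concentrations per (window, analyte).

    Only included samples contribute; an empty window yields a row with n = 0
    and missing statistics.
    """
    inc = samples[samples["included"] == 1]
    windows = sorted(samples["window_index"].unique())
    rows = []
    for w in windows:
        grp = inc[inc["window_index"] == w]
        for name in analytes:
            vals = grp[f"{name}_ug_per_g"].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                stats_ = dict(median=np.nan, p25=np.nan, p75=np.nan,
                              min=np.nan, max=np.nan)
            else:
                q = np.quantile(vals, [0.25, 0.5, 0.75], method=method)
                stats_ = dict(median=q[1], p25=q[0], p75=q[2],
                              min=vals.min(), max=vals.max())
            rows.append({"window_index": w, "analyte": name, "n": len(vals),
                         **stats_})
    return pd.DataFrame(rows)


def relative_change(samples: pd.DataFrame, analyte: str,
                    from_window: int = 2, to_window: int = 4
                    ) -> tuple[pd.DataFrame, float, int]:
    """Per sample-set concentration ratio c_to/c_from and its median.

    Sets lacking either window (or with it excluded) are skipped; the skip
    count is returned alongside the per-set ratios and their median.
    """
    inc = samples[samples["included"] == 1]
    col = f"{analyte}_ug_per_g"
    ratios = []
    skipped = 0
    for (subj, sess), grp in inc.groupby(["subject_id", "session_id"], sort=True):
        a = grp.loc[grp["window_index"] == from_window, col]
        b = grp.loc[grp["window_index"] == to_window, col]
        if len(a) == 1 and len(b) == 1 and a.iloc[0] > 0:
            ratios.append({"subject_id": subj, "session_id": sess,
                           "ratio": float(b.iloc[0] / a.iloc[0])})
        else:
            skipped += 1
    df = pd.DataFrame(ratios)
    med = float(df["ratio"].median()) if len(df) else math.nan
    return df, med, skipped


def metabolite_proportions(medians: pd.DataFrame) -> pd.DataFrame:
    """Per-window percentage share of each analyte in the summed medians.

    ``medians``: wide frame indexed by window with one column per analyte
    (typically the three naphthalene metabolites). Shares sum to 100 per
    window; a zero-sum window raises.
    """
    totals = medians.sum(axis=1)
    if (totals <= 0).any() or medians.lt(0).any().any():
        raise ValueError("medians must be non-negative with positive window sums")
    return 100.0 * medians.div(totals, axis=0)


def log_pearson(samples: pd.DataFrame, pair: tuple[str, str]) -> CorrelationResult:
    """Pearson correlation between natural-log concentrations of two analytes.

    Pools all included samples across subjects, sessions and windows. Values
    are strictly positive after LOD substitution, so logs are well defined.
    """
    inc = samples[samples["included"] == 1]
    x = np.log(inc[f"{pair[0]}_ug_per_g"].to_numpy(dtype=float))
    y = np.log(inc[f"{pair[1]}_ug_per_g"].to_numpy(dtype=float))
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in log concentrations")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(analyte_pair=tuple(pair), n=len(x),
                             r=float(r), p=float(p))
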