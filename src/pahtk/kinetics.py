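"""Elimination kinetics: peak identification, decay records, the mixed-effects
exponential-decay fit and derived half-lives.

The concentration course after a single exposure is modelled as
C(t) = C0 + B * exp(lambda * t) + error, with C0 the pre-exposure baseline,
B the peak-minus-baseline amplitude and t the time since the peak. Taking
logs of the baseline-subtracted concentration makes this linear,
ln(C - C0) = ln B + lambda * t, and the slope is estimated jointly for all
biomarkers by the mixed model in :mod:`pahtk.lmm`. The half-life is
ln 2 / (-lambda).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import LN2
from .lmm import DecayLMM, LMMResult, MixedModelSpec

__all__ = [
    "DecayRecord", "BiomarkerKinetics", "KineticFit", "TimeToBaseline",
    "locate_peak", "build_decay_records", "fit_eq1_mixed", "derive_half_lives",
    "half_life_interval", "time_to_baseline", "summarize_time_to_peak",
    "fit_from_samples",
]

POST_EXPOSURE_WINDOWS = tuple(range(3, 10))


@dataclass(frozen=True)
class DecayRecord:
    """One post-peak observation transformed for the log-linear decay fit."""

    subject_id: str
    session_id: int
    biomarker: str
    t: float  # h since the set's peak (midpoint time scale)
    C: float  # ug/g creatinine
    C0: float  # baseline, ug/g creatinine

    @property
    def y(self) -> float:
        return math.log(self.C - self.C0)


@dataclass
class BiomarkerKinetics:
    biomarker: str
    lam: float
    se: float
    ci_low: float
    ci_high: float
    half_life: float
    hl_ci_low: float
    hl_ci_high: float
    n_records: int
    valid: bool  # lambda < 0, so the half-life is finite and positive


@dataclass
class KineticFit:
    biomarkers: dict[str, BiomarkerKinetics]
    varcomps: dict[str, float]
    loglik: float
    converged: bool
    message: str
    n_records: int
    dropped: dict[str, int]
    boundary: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "biomarkers": {k: asdict(v) for k, v in self.biomarkers.items()},
            "varcomps": self.varcomps,
            "loglik": self.loglik,
            "converged": self.converged,
            "message": self.message,
            "n_records": self.n_records,
            "dropped": self.dropped,
            "boundary": self.boundary,
        }


@dataclass(frozen=True)
class TimeToBaseline:
    n_halvings: float
    hours: float
    hours_rounded_n: float  # round(n_halvings) * half_life convenience product


def locate_peak(sample_set: pd.DataFrame, biomarker: str,
                windows: Sequence[int] = POST_EXPOSURE_WINDOWS) -> dict | None:
    """Maximum adjusted concentration among included post-exposure samples.

    Returns a dict with the anchor-time peak (``t_peak``), the midpoint-scale
    peak time (``t_mid_peak``), the concentration and the window index, or
    None when the set has no eligible sample. Ties break to the earliest time.
    """
    col = f"{biomarker}_ug_per_g"
    elig = sample_set[(sample_set["included"] == 1)
                      & sample_set["window_index"].isin(windows)
                      & sample_set[col].notna()]
    if len(elig) == 0:
        return None
    elig = elig.sort_values("time_h", kind="mergesort")
    i = int(np.argmax(elig[col].to_numpy()))  # argmax takes the first maximum
    row = elig.iloc[i]
    return {
        "t_peak": float(row["time_h"]),
        "t_mid_peak": float(row["t_mid_h"]) if "t_mid_h" in row else float(row["time_h"]),
        "c_peak": float(row[col]),
        "window_index": int(row["window_index"]),
    }


def _baseline(sample_set: pd.DataFrame, biomarker: str,
              baseline_window: int, fallback_window: int) -> float | None:
    col = f"{biomarker}_ug_per_g"
    for w in (baseline_window, fallback_window):
        row = sample_set[(sample_set["window_index"] == w)
                         & (sample_set["included"] == 1)]
        if len(row) == 1 and np.isfinite(row[col].iloc[0]):
            return float(row[col].iloc[0])
    return None


def build_decay_records(samples: pd.DataFrame, biomarkers: Sequence[str],
                        baseline_window: int = 2, fallback_window: int = 1
                        ) -> tuple[list[DecayRecord], dict, pd.DataFrame]:
    """Transform included post-peak samples to (t since peak, ln(C - C0)).

    Per (subject, session, biomarker): the baseline C0 is the set's
    baseline-window adjusted concentration (fallback to the earlier window);
    records are the included samples at or after the peak with C > C0.
    Returns (records, drop accounting, per-set peak table).
    """
    records: list[DecayRecord] = []
    peaks = []
    dropped = {"sets_no_peak": 0, "sets_no_baseline": 0,
               "sets_all_records_nonpositive": 0, "records_nonpositive": 0}
    for (subj, sess), grp in samples.groupby(["subject_id", "session_id"], sort=True):
        for b in biomarkers:
            peak = locate_peak(grp, b)
            if peak is None:
                dropped["sets_no_peak"] += 1
                continue
            c0 = _baseline(grp, b, baseline_window, fallback_window)
            if c0 is None:
                dropped["sets_no_baseline"] += 1
                continue
            peaks.append({"subject_id": subj, "session_id": sess,
                          "biomarker": b, **peak})
            col = f"{b}_ug_per_g"
            post = grp[(grp["included"] == 1)
                       & (grp["time_h"] >= peak["t_peak"])
                       & grp["window_index"].isin(POST_EXPOSURE_WINDOWS)]
            made = 0
            for _, row in post.iterrows():
                c = float(row[col])
                if c <= c0:
                    dropped["records_nonpositive"] += 1
                    continue
                records.append(DecayRecord(
                    subject_id=subj, session_id=int(sess), biomarker=b,
                    t=float(row["t_mid_h"]) - peak["t_mid_peak"], C=c, C0=c0))
                made += 1
            if made == 0:
                dropped["sets_all_records_nonpositive"] += 1
    return records, dropped, pd.DataFrame(peaks)


def _records_frame(records: Sequence[DecayRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "session_id": [r.session_id for r in records],
        "biomarker": [r.biomarker for r in records],
        "t": [r.t for r in records],
        "y": [r.y for r in records],
    })


def fit_eq1_mixed(records: Sequence[DecayRecord] | pd.DataFrame,
                  spec: MixedModelSpec | None = None,
                  dropped: Mapping[str, int] | None = None) -> KineticFit:
    """Fit the decay model as a linear mixed model, all biomarkers jointly."""
    spec = spec or MixedModelSpec()
    df = records if isinstance(records, pd.DataFrame) else _records_frame(records)
    if len(df) < 4:
        raise ValueError("too few decay records to fit")
    model = DecayLMM(df["t"], df["y"], df["biomarker"],
                     df["subject_id"], df["session_id"], spec=spec)
    res = model.fit()
    K = len(model.levels)
    out: dict[str, BiomarkerKinetics] = {}
    for k, b in enumerate(model.levels):
        lam = float(res.beta[K + k])
        se = float(math.sqrt(res.cov_beta[K + k, K + k]))
        lo, hi = lam - 1.959963984540054 * se, lam + 1.959963984540054 * se
        hl, (hl_lo, hl_hi), valid = half_life_interval(lam, lo, hi)
        out[b] = BiomarkerKinetics(
            biomarker=b, lam=lam, se=se, ci_low=lo, ci_high=hi,
            half_life=hl, hl_ci_low=hl_lo, hl_ci_high=hl_hi,
            n_records=int((df["biomarker"] == b).sum()), valid=valid,
        )
    return KineticFit(
        biomarkers=out, varcomps=res.varcomps, loglik=res.loglik,
        converged=res.converged, message=res.message, n_records=len(df),
        dropped=dict(dropped or {}), boundary=res.boundary,
    )


def half_life_interval(lam: float, lo: float, hi: float
                       ) -> tuple[float, tuple[float, float], bool]:
    """Map a slope and its CI to (half-life, CI, valid) via ln2/(-lambda)."""
    if lam >= 0:
        return math.nan, (math.nan, math.nan), False
    hl = LN2 / (-lam)
    hl_lo = LN2 / (-lo)  # most negative lambda -> shortest half-life
    hl_hi = LN2 / (-hi) if hi < 0 else math.inf
    return hl, (hl_lo, hl_hi), True


def derive_half_lives(fit: KineticFit) -> dict[str, tuple[float, tuple[float, float]]]:
    """Per-biomarker (half-life, 95% CI) from the fitted slopes.

    The CI endpoints are the monotone transform ln2/(-lambda) of the slope CI
    endpoints; a slope CI reaching 0 gives an infinite upper half-life.
    """
    return {b: (k.half_life, (k.hl_ci_low, k.hl_ci_high))
            for b, k in fit.biomarkers.items()}


def time_to_baseline(c_peak: float, c_base: float, half_life: float) -> TimeToBaseline:
    """Halvings (log2 of the peak/baseline ratio) and hours back to baseline."""
    if c_base <= 0 or c_peak < c_base:
        raise ValueError("require c_peak >= c_base > 0")
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    n = math.log2(c_peak / c_base)
    return TimeToBaseline(n_halvings=n, hours=n * half_life,
                          hours_rounded_n=round(n) * half_life)


def summarize_time_to_peak(peaks: pd.DataFrame) -> pd.DataFrame:
    """Median and range of anchor-time peaks per biomarker across sets."""
    rows = []
    for b, grp in peaks.groupby("biomarker", sort=True):
        tp = grp["t_peak"].to_numpy(dtype=float)
        rows.append({"biomarker": b, "n_sets": len(tp),
                     "median_h": float(np.median(tp)),
                     "min_h": float(tp.min()), "max_h": float(tp.max())})
    return pd.DataFrame(rows)


def fit_from_samples(samples: pd.DataFrame, biomarkers: Sequence[str],
                     spec: MixedModelSpec | None = None,
                     baseline_window: int = 2
                     ) -> tuple[KineticFit, pd.DataFrame, pd.DataFrame]:
    """Samples table -> (KineticFit, time-to-peak summary, per-set peaks)."""
    fallback = 1 if baseline_window != 1 else 2
    records, dropped, peaks = build_decay_records(
        samples, biomarkers, baseline_window=baseline_window,
        fallback_window=fallback)
    fit = fit_eq1_mixed(records, spec=spec, dropped=dropped)
    return fit, summarize_time_to_peak(peaks), peaks
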