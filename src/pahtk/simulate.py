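"""Synthetic spot-urine generator.

Each training session delivers a single dose into a first-order absorption
depot at the midpoint of exposure; the body burden then follows the Bateman
profile X(t) = dose*ka/(ka-ke) * (exp(-ke*t) - exp(-ka*t)). Urinary excretion
of a metabolite is fe*ke*X(t) plus a constant subject-specific background
rate, and a void's concentration is the mass excreted since the previous void
divided by the void volume, so total mass is conserved exactly across any
partition of the day into voids.

Randomness uses one master seed with per-subject and per-(subject, session)
substreams, so enlarging the cohort never perturbs existing subjects.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalyteConfig, DegenerateKineticsError, StudyDesign

__all__ = [
    "Void", "body_burden", "excreted_amount", "apply_assay",
    "simulate_study", "voids_to_frame", "simulate_frame",
]


@dataclass
class Void:
    """A single urination event."""

    subject_id: str
    session_id: int
    time: float  # h relative to exposure onset
    volume: float  # L
    creatinine_conc: float  # g/L
    true_conc: dict[str, float] = field(default_factory=dict)  # ug/L
    meas_conc: dict[str, float] = field(default_factory=dict)  # ug/L
    below_lod: dict[str, bool] = field(default_factory=dict)
    scheduled: bool = True
    window_index: int | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("void volume must be positive")
        if self.scheduled != (self.window_index is not None):
            raise ValueError("scheduled voids and only those carry a window index")


def body_burden(t, dose: float, ka: float, ke: float):
    """Amount of analyte in the body at time ``t`` after the dose (Bateman).

    ``t`` may be a scalar or array; times before the dose return 0. The profile
    rises with rate ``ka``, falls with terminal rate ``ke`` and peaks at
    ln(ka/ke)/(ka-ke).
    """
    if math.isclose(ka, ke, rel_tol=1e-9, abs_tol=0.0):
        raise DegenerateKineticsError("ka == ke: Bateman profile is degenerate")
    t = np.asarray(t, dtype=float)
    tt = np.clip(t, 0.0, None)
    x = dose * ka / (ka - ke) * (np.exp(-ke * tt) - np.exp(-ka * tt))
    x = np.where(t < 0, 0.0, np.clip(x, 0.0, None))
    return float(x) if x.ndim == 0 else x


def _cumulative_pulse(t: float, dose: float, ka: float, ke: float, fe: float) -> float:
    """fe*ke*Integral_0^t X(u) du, closed form; 0 for t <= 0, fe*dose as t->inf."""
    if t <= 0:
        return 0.0
    integral = (1.0 - math.exp(-ke * t)) / ke - (1.0 - math.exp(-ka * t)) / ka
    return fe * ke * dose * ka / (ka - ke) * integral


def excreted_amount(t0: float, t1: float, analyte: AnalyteConfig, dose: float,
                    dose_time: float = 0.0, *, ke: float | None = None,
                    baseline_rate: float | None = None) -> float:
    """Analyte mass (ug) excreted in urine over the interval (t0, t1].

    Sum of the constant background excretion and the exposure pulse
    (first-order absorption starting at ``dose_time``). Additive over adjacent
    intervals by construction. ``ke``/``baseline_rate`` may override the
    analyte defaults (used for subject-level variability).
    """
    if not t0 < t1:
        raise ValueError("require t0 < t1")
    ke = analyte.ke if ke is None else ke
    base = analyte.baseline_rate if baseline_rate is None else baseline_rate
    if math.isclose(analyte.ka, ke, rel_tol=1e-9, abs_tol=0.0):
        raise DegenerateKineticsError("ka == ke: use distinct rate constants")
    pulse = (_cumulative_pulse(t1 - dose_time, dose, analyte.ka, ke, analyte.fe)
             - _cumulative_pulse(t0 - dose_time, dose, analyte.ka, ke, analyte.fe))
    return base * (t1 - t0) + pulse


def _sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    s = _sigma(cv)
    return float(rng.lognormal(mean=-0.5 * s * s, sigma=s))


def apply_assay(true_conc: float, analyte: AnalyteConfig,
                rng: np.random.Generator) -> tuple[float, bool]:
    """Measure a concentration: multiplicative lognormal assay noise + LOD flag.

    The raw measured value is returned even when flagged below the limit of
    detection (substitution happens in preprocessing).
    """
    if true_conc < 0:
        raise ValueError("true concentration must be non-negative")
    measured = true_conc * _lognormal_factor(rng, analyte.assay_cv)
    return measured, bool(measured < analyte.lod)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    )


def _scheduled_times(design: StudyDesign, rng: np.random.Generator) -> list[float]:
    """One draw per window, uniform in its range, forced strictly increasing."""
    times: list[float] = []
    prev = -math.inf
    for w in design.windows:
        lo = max(w.t_min, prev + 0.05)
        hi = w.t_max
        if lo >= hi:  # overlapping windows squeezed shut; nudge just above prev
            lo = prev + 0.01
            hi = lo + 0.02
        t = float(rng.uniform(lo, hi))
        times.append(t)
        prev = t
    return times


def simulate_study(design: StudyDesign, analytes: Sequence[AnalyteConfig] | Mapping[str, AnalyteConfig],
                   seed: int) -> list[Void]:
    """Generate the full void-level dataset for one campaign.

    Returns voids ordered by subject, session, time. Scheduled voids carry
    their window index; unscheduled voids arise from a Poisson process between
    the first and last scheduled void of each session.
    """
    if isinstance(analytes, Mapping):
        analytes = list(analytes.values())
    else:
        analytes = list(analytes)
    voids: list[Void] = []
    for si in range(design.n_subjects):
        subject_id = f"S{si + 1}"
        srng = _stream(seed, si)
        base_mult = {a.name: _lognormal_factor(srng, design.baseline_subject_cv)
                     for a in analytes}
        creat_mult = _lognormal_factor(srng, design.creatinine_subject_cv)
        ke_mult = _lognormal_factor(srng, design.ke_subject_cv)
        for se in range(design.n_sessions):
            rng = _stream(seed, si, se)
            # shared session exposure intensity across analytes
            z = float(rng.standard_normal())
            dose = {}
            for a in analytes:
                s = _sigma(a.dose_cv)
                dose[a.name] = a.dose_mean * math.exp(s * z - 0.5 * s * s)
            sched = _scheduled_times(design, rng)
            span = sched[-1] - sched[0]
            n_uns = (int(rng.poisson(design.unscheduled_void_rate * span))
                     if design.unscheduled_void_rate > 0 else 0)
            uns = sorted(float(u) for u in rng.uniform(sched[0], sched[-1], size=n_uns))
            events = sorted(
                [(t, w.index) for t, w in zip(sched, design.windows)]
                + [(t, None) for t in uns]
            )
            prev_t = sched[0] - design.overnight_gap_h
            for t, widx in events:
                dt = t - prev_t
                if dt <= 1e-9:  # coincident unscheduled draw; skip it
                    continue
                volume = design.urine_flow_mean * dt * _lognormal_factor(rng, design.volume_cv)
                creat_mass = (design.creatinine_rate_mean * creat_mult * dt
                              * _lognormal_factor(rng, design.creatinine_void_cv))
                true_conc, meas_conc, below = {}, {}, {}
                for a in analytes:
                    ke_s = min(a.ke * ke_mult, 0.9 * a.ka)  # keep absorption-limited
                    mass = excreted_amount(
                        prev_t, t, a, dose[a.name], dose_time=design.dose_time,
                        ke=ke_s, baseline_rate=a.baseline_rate * base_mult[a.name],
                    )
                    c = mass / volume
                    true_conc[a.name] = c
                    m, b = apply_assay(c, a, rng)
                    meas_conc[a.name] = m
                    below[a.name] = b
                voids.append(Void(
                    subject_id=subject_id, session_id=se + 1, time=t,
                    volume=volume, creatinine_conc=creat_mass / volume,
                    true_conc=true_conc, meas_conc=meas_conc, below_lod=below,
                    scheduled=widx is not None, window_index=widx,
                ))
                prev_t = t
    return voids


def voids_to_frame(voids: Iterable[Void], analyte_names: Sequence[str]) -> pd.DataFrame:
    """Long-format void table (one row per void, per-analyte columns)."""
    rows = []
    for v in voids:
        row = {
            "subject_id": v.subject_id,
            "session_id": v.session_id,
            "time_h": v.time,
            "volume_L": v.volume,
            "creatinine_g_per_L": v.creatinine_conc,
            "scheduled": int(v.scheduled),
            "window_index": v.window_index if v.window_index is not None else pd.NA,
        }
        for name in analyte_names:
            row[f"{name}_true_ug_per_L"] = v.true_conc[name]
            row[f"{name}_meas_ug_per_L"] = v.meas_conc[name]
            row[f"{name}_below_lod"] = int(v.below_lod[name])
        rows.append(row)
    df = pd.DataFrame(rows)
    df["window_index"] = df["window_index"].astype("Int64")
    return df


def simulate_frame(design: StudyDesign, analytes: Mapping[str, AnalyteConfig],
                   seed: int) -> pd.DataFrame:
    """Convenience wrapper: :func:`simulate_study` as a DataFrame."""
    return voids_to_frame(simulate_study(design, analytes, seed), list(analytes))
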