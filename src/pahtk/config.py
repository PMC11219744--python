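"""Study configuration: analyte assay/kinetic parameters and the sampling design.

The default configuration (``study_defaults.yaml``) encodes a repeated
spot-urine biomonitoring campaign around short live-fire training exposures:
6 subjects x 5 sessions x 9 scheduled samplings spanning roughly -5 h to
+21 h around exposure onset, with four urinary PAH metabolites
(DHN = 1,2-dihydroxynaphthalene, 1-/2-hydroxynaphthalene, 1-hydroxypyrene).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

LN2 = math.log(2.0)

#: canonical analyte keys, in reporting order
ANALYTES = ("DHN", "NAP1", "NAP2", "PYR1")

#: pretty names used in tables and figures
DISPLAY_NAMES = {"DHN": "DHN", "NAP1": "1-NAP", "NAP2": "2-NAP", "PYR1": "1-PYR"}


class DegenerateKineticsError(ValueError):
    """Raised when absorption and elimination rate constants coincide."""


@dataclass(frozen=True)
class AnalyteConfig:
    """Assay properties and one-compartment generator truth for one analyte.

    Parameters
    ----------
    name : str
        Analyte key (one of :data:`ANALYTES`).
    lod : float
        Assay limit of detection, ug/L.
    assay_cv : float
        Between-day analytical imprecision as a coefficient of variation.
    baseline_rate : float
        Background urinary excretion rate, ug/h.
    dose_mean : float
        Mean exposure-attributable amount absorbed per session, ug
        (expressed directly as metabolite equivalents; see ``fe``).
    dose_cv : float
        Between-session lognormal variability of the dose.
    ka : float
        First-order absorption rate constant, 1/h.
    ke : float
        Terminal first-order elimination rate constant, 1/h.
    fe : float
        Fraction of the absorbed dose excreted as this metabolite.
    """

    name: str
    lod: float
    assay_cv: float
    baseline_rate: float
    dose_mean: float
    dose_cv: float
    ka: float
    ke: float
    fe: float = 1.0

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise ValueError("lod must be positive")
        if self.assay_cv < 0:
            raise ValueError("assay_cv must be non-negative")
        if not (self.ka > self.ke > 0):
            raise ValueError("require ka > ke > 0")
        if not (0 < self.fe <= 1):
            raise ValueError("fe must be in (0, 1]")
        if self.dose_mean < 0 or self.dose_cv < 0 or self.baseline_rate < 0:
            raise ValueError("rates and doses must be non-negative")

    @property
    def half_life(self) -> float:
        """Terminal elimination half-life ln2/ke, hours."""
        return LN2 / self.ke

    @property
    def display(self) -> str:
        return DISPLAY_NAMES.get(self.name, self.name)


@dataclass(frozen=True)
class SamplingWindow:
    """One scheduled sampling occasion, hours relative to exposure onset."""

    index: int
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(f"window {self.index}: t_min must be < t_max")

    @property
    def t_mean(self) -> float:
        return 0.5 * (self.t_min + self.t_max)


# Scheduled sampling windows of the emulated campaign: morning urine on the
# training day, immediately pre/post training, and 1/3/6/9 h, bedtime and
# next-morning samples (ranges of observed sampling times).
DEFAULT_WINDOWS = (
    SamplingWindow(1, -5.3, -2.3),
    SamplingWindow(2, -1.0, -0.1),
    SamplingWindow(3, 1.5, 2.4),
    SamplingWindow(4, 2.5, 3.6),
    SamplingWindow(5, 4.5, 5.6),
    SamplingWindow(6, 7.4, 8.6),
    SamplingWindow(7, 9.6, 12.8),
    SamplingWindow(8, 11.6, 14.1),
    SamplingWindow(9, 18.2, 21.8),
)


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout and urine-production model for the synthetic generator."""

    n_subjects: int = 6
    n_sessions: int = 5
    windows: tuple[SamplingWindow, ...] = DEFAULT_WINDOWS
    exposure_onset: float = 0.0
    exposure_duration: float = 0.75
    unscheduled_void_rate: float = 0.08  # voids/h between first and last window
    urine_flow_mean: float = 0.065  # L/h
    volume_cv: float = 0.35  # per-void lognormal noise on volume
    overnight_gap_h: float = 7.5  # accumulation interval feeding the first void
    creatinine_rate_mean: float = 0.0625  # g/h (~1.5 g/day)
    creatinine_subject_cv: float = 0.2
    creatinine_void_cv: float = 0.3
    baseline_subject_cv: float = 0.5  # between-subject background excretion
    ke_subject_cv: float = 0.2  # between-subject elimination variability

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("need at least one subject and one session")
        if len(self.windows) != 9:
            raise ValueError("the design uses exactly 9 sampling windows")
        idx = [w.index for w in self.windows]
        if idx != sorted(idx):
            raise ValueError("windows must be ordered by index")
        means = [w.t_mean for w in self.windows]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("window mean times must increase with index")
        for name in ("unscheduled_void_rate", "urine_flow_mean", "volume_cv",
                     "overnight_gap_h", "creatinine_rate_mean",
                     "creatinine_subject_cv", "creatinine_void_cv",
                     "baseline_subject_cv", "ke_subject_cv",
                     "exposure_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.urine_flow_mean <= 0 or self.creatinine_rate_mean <= 0:
            raise ValueError("urine flow and creatinine rate must be positive")

    @property
    def dose_time(self) -> float:
        """Time at which the absorbed dose enters the depot (exposure midpoint)."""
        return self.exposure_onset + 0.5 * self.exposure_duration

    def window(self, index: int) -> SamplingWindow:
        for w in self.windows:
            if w.index == index:
                return w
        raise KeyError(index)


def _design_from_dict(d: Mapping) -> StudyDesign:
    d = dict(d)
    wins = d.pop("windows", None)
    kwargs = dict(d)
    if wins is not None:
        kwargs["windows"] = tuple(
            SamplingWindow(int(w["index"]), float(w["t_min"]), float(w["t_max"]))
            for w in wins
        )
    return StudyDesign(**kwargs)


def _analytes_from_dict(d: Mapping) -> dict[str, AnalyteConfig]:
    return {name: AnalyteConfig(name=name, **spec) for name, spec in d.items()}


def design_to_dict(design: StudyDesign) -> dict:
    out = {
        k: getattr(design, k)
        for k in (
            "n_subjects", "n_sessions", "exposure_onset", "exposure_duration",
            "unscheduled_void_rate", "urine_flow_mean", "volume_cv",
            "overnight_gap_h", "creatinine_rate_mean", "creatinine_subject_cv",
            "creatinine_void_cv", "baseline_subject_cv", "ke_subject_cv",
        )
    }
    out["windows"] = [
        {"index": w.index, "t_min": w.t_min, "t_max": w.t_max} for w in design.windows
    ]
    return out


def analytes_to_dict(analytes: Mapping[str, AnalyteConfig]) -> dict:
    return {
        a.name: {
            k: getattr(a, k)
            for k in ("lod", "assay_cv", "baseline_rate", "dose_mean",
                      "dose_cv", "ka", "ke", "fe")
        }
        for a in analytes.values()
    }


def load_params(path: str | None = None) -> tuple[StudyDesign, dict[str, AnalyteConfig]]:
    """Load a (design, analytes) pair from YAML; packaged defaults if ``path`` is None."""
    if path is None:
        text = resources.files("pahtk").joinpath("study_defaults.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return _design_from_dict(raw.get("design", {})), _analytes_from_dict(raw["analytes"])


def default_design() -> StudyDesign:
    return load_params()[0]


def default_analytes() -> dict[str, AnalyteConfig]:
    return load_params()[1]


def dump_params(design: StudyDesign, analytes: Mapping[str, AnalyteConfig], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"design": design_to_dict(design), "analytes": analytes_to_dict(analytes)},
            fh, sort_keys=False,
        )
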