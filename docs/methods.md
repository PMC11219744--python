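# Methods

## Scope and data model

The package analyses spot-urine biomonitoring campaigns in which a small
cohort is sampled repeatedly around a short, well-defined exposure to PAHs.
A *void* is a single urination event (time, volume, creatinine, per-analyte
concentrations); a *sample* is a scheduled sampling occasion, possibly
pooled from several voids; a *sample set* is the nine samples covering ~24 h
around one exposure session for one subject. All tabular interchange is CSV
with a leading `# meta:` comment carrying the seed, a configuration hash and
the package version, so every artifact is reproducible from its inputs.

## Synthetic campaign generator

Because raw campaign data of this kind are rarely shareable, the generator
is a first-class, tested component that produces void-level datasets with
the statistical and kinetic structure the analysis assumes.

**Kinetic core.** Each session delivers a single dose into a first-order
depot at the midpoint of the exposure interval. The body burden follows the
Bateman profile `X(t) = dose·ka/(ka−ke)·(e^{−ke t} − e^{−ka t})`; urinary
excretion of a metabolite is `fe·ke·X(t)` plus a constant subject-specific
background rate. A void's concentration is the closed-form mass excreted
since the previous void divided by the void volume, so any partition of the
day into voids conserves mass exactly, and pooling voids is exact physical
mixing. The terminal log-slope of the concentration course is `−ke` by
construction; `ln2/ke` is the true half-life that the downstream fit is
meant to recover.

**Default conditions** (`study_defaults.yaml`): 6 subjects × 5 sessions ×
9 sampling windows whose time ranges reproduce a morning-urine /
pre-training / post-training / 1–9 h / bedtime / next-morning protocol.
Assay limits of detection are 0.3 µg/L (DHN), 0.1 µg/L (naphthols) and
0.02 µg/L (1-hydroxypyrene); between-day assay CVs 9.4% (DHN) and 14%
(mono-hydroxy metabolites), applied as unit-mean multiplicative lognormal
noise. True half-lives are 6.6/6.2/5.2/7.7 h. Absorption constants are
2.0 h⁻¹ (naphthalene metabolites) and 0.9 h⁻¹ (1-hydroxypyrene): fast
enough that absorption is essentially complete before the first post-peak
sample (the deviation of the log course from the terminal slope at the
burden peak is `ln(1−ke/ka)`, decaying at rate `ka−ke`), yet slow enough
that the noise-free concentration peak falls in the intended window
(window 4, ~3 h, for the naphthalene metabolites; window 5, ~5 h, for
1-hydroxypyrene). Doses (92/7.7/5.7/0.31 µg metabolite-equivalents, `fe`=1)
and baseline rates (0.175/0.031/0.123/0.0034 µg/h) were sized once so that
pre-exposure and peak creatinine-adjusted medians have the magnitudes
typical of live-fire training exposures (DHN ~2–3 and ~130 µg/g).

**Physiological variability** (all lognormal, unit mean): between-subject
background excretion CV 0.5; between-subject elimination-rate multiplier
CV 0.2, shared across analytes (human elimination half-lives typically vary
by ~20–30% between individuals; this also keeps the model's random slope
meaningful); between-session exposure intensity CV 0.5, drawn once per
session and shared across analytes (a common smoke-intensity factor);
creatinine excretion 1.5 g/day with subject CV 0.2 and per-void CV 0.3;
urine flow 0.065 L/h with per-void volume CV 0.35. Unscheduled voids arise
from a 0.08 h⁻¹ Poisson process between the first and last scheduled void.
The first (morning) void accumulates over a 7.5 h overnight gap. Randomness
derives from one master seed with per-subject and per-(subject, session)
substreams, so enlarging the cohort never perturbs existing subjects.

**What the generator does not emulate:** metabolic branching between the
naphthalene metabolites (each analyte carries its own effective dose),
carry-over between sessions (≥6 days apart in the emulated protocol),
circadian patterns beyond the overnight accumulation, diet/smoking
confounders, and biphasic elimination. Passing tests therefore demonstrate
correctness of the analysis chain under a clean one-compartment truth, not
robustness to those real-data features.

## Preprocessing

Unscheduled voids are merged into the *next* scheduled sample by
volume-weighted mixing (concentration `Σc_iV_i/ΣV_i` for analytes and
creatinine); the below-LOD flag is re-evaluated on the pooled measured
concentration, because assays in such protocols run on the pooled physical
sample. Censored concentrations are substituted by LOD/2 (idempotent), then
divided by creatinine (µg/g). Samples with creatinine outside 0.3–3.0 g/L
are flagged rather than deleted; the bounds are inclusive (the conventional
reading of the WHO validity range). Excluded and missing samples are
reconciled in an accounting report (`included + excluded = collected =
expected − missing`).

**Time axes.** Each sample keeps its protocol *anchor time* (the scheduled
void) and additionally the *collection-interval midpoint* `t_mid_h`
(midpoint between consecutive collected samples; the first sample uses its
own time). A spot concentration is the average excretion over its
collection interval, so regressing log concentration on anchor times is
biased shallow by the factor `ln((e^{keΔt}−1)/(keΔt))` — about 15–18% over
this schedule, dominated by the long overnight interval — whereas the
midpoint abscissa is unbiased to ~2%. The decay fit therefore uses
midpoints, while time-to-peak summaries keep the anchor convention of the
sampling protocol.

## Decay model and estimation

Per sample set and biomarker, the peak is the maximum adjusted
concentration among included post-exposure samples (windows 3–9), ties to
the earliest; the baseline `C0` is the set's window-2 concentration
(window 2 is drawn immediately before the exposure), falling back to
window 1. Records are the included samples at or after the peak with
`C > C0` (records at or below baseline are dropped and counted — flooring
them would fabricate data); the outcome is `y = ln(C − C0)` at `t` = time
since the peak (midpoint scale). The peak record itself (t = 0) is
included.

The mixed model has fixed effects `biomarker + biomarker:t` (per-biomarker
`ln B` and `λ`), a correlated participant-level random intercept/slope
pair (unstructured 2×2 covariance), a session-within-participant random
intercept (the natural reading for a design where every participant
completes several sessions), and residual AR(1) correlation `φ^|i−j|`
within each time-ordered subject–session–biomarker series (a
continuous-time variant `φ^|t_i−t_j|`, with `φ∈(0,1)`, is available by
configuration because sampling is unevenly spaced). REML is the default;
the likelihood is assembled and Cholesky-factorized per participant (the
independence block), fixed effects are profiled out by GLS, and the
optimizer (L-BFGS-B with a Nelder–Mead fallback) works on log standard
deviations and atanh/logit-transformed `φ` from fixed data-derived starting
values, so fits are deterministic. Convergence tolerance is 1e-8 on the
objective; variances may pin at an effective-zero boundary and are then
reported as such. Wald standard errors come from `(X'V̂⁻¹X)⁻¹`; 95% CIs on
`λ` are normal-based and mapped monotonically to half-life CIs via
`ln2/(−λ)`.

Correctness is established three ways: the blocked likelihood equals a
brute-force dense multivariate-normal evaluation on small instances to
1e-6; degenerate settings reduce to closed-form OLS/GLS to 1e-8 and to
statsmodels' REML for the compound-symmetry case; and parameter-recovery
replicates at the default study scale return the configured half-lives.

## Descriptives

Percentiles use linear interpolation between order statistics
(`h = (n−1)p + 1`, numpy's default); the weighted-average convention
(`h = (n+1)p`, `weibull`) is available because commercial packages differ
in the quartile rule (medians agree). Relative changes are per-set
concentration ratios aggregated as medians, with sets lacking either window
skipped and counted. Metabolite proportions are percentage shares of the
per-window median sum, reported to the nearest integer when quoted in text.
Correlations pool all included samples across subjects, sessions and
windows on the natural-log scale, with two-sided p from the t transform.

## Known limitations

- With only six participants, normal-based Wald CIs on `λ` undercover
  somewhat: over 200 default-scale replicates, coverage of the true
  half-life is ~92% (DHN) but drops to ~80% for the fastest-eliminating,
  lowest-amplitude analyte (2-naphthol), where peak-selection (the t = 0
  record is the maximum of noisy neighbours) and the concavity of
  `ln(C − C0)` under noisy baseline subtraction bias the slope slightly
  steep (point estimates remain within ~5–10% of truth). Profile-likelihood
  or small-sample-t intervals would widen coverage but are not the
  estimator this pipeline standardizes on.
- The fit targets the first (monophasic) elimination phase only; a slower
  second phase, if present, is outside the observation span.
- Creatinine adjustment is the only dilution correction (no specific
  gravity or osmolality), and excretion rates (µg/h) are not computed.
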