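# pahtk — urinary PAH biomarker toxicokinetics from spot-urine biomonitoring

`pahtk` is a tested pipeline for occupational-health studies that monitor
polycyclic aromatic hydrocarbon (PAH) uptake through urinary metabolites —
the setting it emulates is firefighting instructors sampled repeatedly around
short live-fire training exposures. It covers the full chain from raw spot
urine voids to elimination half-lives:

- **Synthetic campaign generator** — 6 subjects × 5 sessions × 9 scheduled
  samplings (morning urine, pre/post training, 1/3/6/9 h post, bedtime, next
  morning), unscheduled voids pooled into the next scheduled sample, four
  analytes (DHN = 1,2-dihydroxynaphthalene, 1-/2-hydroxynaphthalene,
  1-hydroxypyrene) with realistic limits of detection and assay imprecision.
  Excretion follows a one-compartment model with first-order absorption and
  elimination (Bateman profile) on top of a constant background rate, so
  mass balance holds exactly across voids.
- **Preprocessing** — volume-weighted pooling, substitution of censored
  values by LOD/2, creatinine adjustment (µg/L ÷ g/L → µg/g), and the
  0.3–3.0 g/L creatinine validity filter with auditable sample accounting.
- **Descriptives** — per-window concentration percentiles, median relative
  changes between samplings, metabolite proportions, Pearson correlations of
  log concentrations, and a concentration–time figure.
- **Kinetics** — per-set peak location, transformation to post-peak decay
  records, and a linear mixed-effects fit of the decay model with AR(1)
  residuals, yielding per-biomarker elimination half-lives with 95% CIs.

## The model

Post-peak concentrations are modelled as

    C(t) = C0 + B · e^{λt} + ε,

where `C` is the creatinine-adjusted concentration, `C0` the pre-exposure
baseline, `B` the peak-minus-baseline amplitude, `t` the time since the
peak, and `λ < 0` the first-order elimination rate constant. Taking logs of
the baseline-subtracted concentration gives the linear form
`ln(C − C0) = ln B + λt`, which is fitted jointly for all biomarkers as a
linear mixed model: fixed per-biomarker intercepts and slopes, a correlated
participant-level random intercept/slope pair, a session-within-participant
random intercept, and residuals that follow an AR(1) process within each
time-ordered subject–session–biomarker series. Estimation is REML over a
blocked marginal Gaussian likelihood (verified against a dense
multivariate-normal oracle and against `nlme`-style reductions); the
half-life is `t½ = ln 2 / (−λ)` with the CI mapped through the same
transform.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(equivalently: `pahtk run --seed 17 --out results`):

```bash
python analysis/01_simulate.py      # results/voids.csv
python analysis/02_preprocess.py    # results/samples.csv, accounting.json
python analysis/03_descriptives.py  # window_percentiles/proportions/correlations.csv
python analysis/04_kinetics.py      # results/kinetics.json, half_lives.csv
python analysis/05_report.py        # results/report.md
```

With the default seed 17 the kinetics stage prints:

```
decay fit: 620 records, converged=True, phi=0.061
  DHN: time to peak median 3.4 h (range 2.6-12.8); half-life 6.2 h (95% CI 5.2-7.5)
  1-NAP: time to peak median 3.4 h (range 1.6-9.7); half-life 5.9 h (95% CI 5.0-7.1)
  2-NAP: time to peak median 4.6 h (range 2.6-11.0); half-life 4.2 h (95% CI 3.7-4.9)
  1-PYR: time to peak median 5.0 h (range 2.6-12.8); half-life 6.1 h (95% CI 5.2-7.6)
```

Each line is one biomarker: the median (and range) of the time from exposure
onset to the maximum creatinine-adjusted concentration across the 30
subject–session sample sets, and the population elimination half-life from
the mixed-model slope. The generator's true half-lives are 6.6, 6.2, 5.2 and
7.7 h; single-campaign estimates scatter around those values (here 6.2, 5.9,
4.2, 6.1 h). The report stage additionally projects the return to baseline —
with this seed, 5.1 halvings ≈ 31 h from the median peak (120.7 µg/g) back
to the pre-exposure median (3.6 µg/g).

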