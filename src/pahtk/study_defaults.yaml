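# Default study conditions for the synthetic spot-urine generator.
#
# Design: 6 firefighting instructors x 5 live-fire training sessions, 9 scheduled
# urine samplings per session (morning urine, pre-training, post-training, then
# 1/3/6/9 h post, bedtime, next morning). Window limits are hours relative to
# exposure onset.
#
# Analytes: per-analyte assay limits of detection and between-day imprecision,
# plus the one-compartment generator truth. ke is the terminal elimination rate
# constant (ln2/ke = 6.6, 6.2, 5.2 and 7.7 h for DHN, 1-NAP, 2-NAP, 1-PYR).
# ka is set so the noise-free observed concentration peak lands in window 4
# (~3 h) for the naphthalene metabolites and window 5 (~5 h) for 1-PYR while
# keeping absorption essentially complete before the first post-peak sample
# (ka >> ke), so the post-peak phase is governed by the terminal slope that
# the decay model estimates.
# Baseline rates and doses are sized to reproduce the order of magnitude of the
# observed pre-exposure and peak creatinine-adjusted medians (e.g. DHN ~2-3 and
# ~134 ug/g creatinine) given the mean creatinine excretion of 1.5 g/day.
design:
  n_subjects: 6
  n_sessions: 5
  windows:
    - {index: 1, t_min: -5.3, t_max: -2.3}
    - {index: 2, t_min: -1.0, t_max: -0.1}
    - {index: 3, t_min: 1.5, t_max: 2.4}
    - {index: 4, t_min: 2.5, t_max: 3.6}
    - {index: 5, t_min: 4.5, t_max: 5.6}
    - {index: 6, t_min: 7.4, t_max: 8.6}
    - {index: 7, t_min: 9.6, t_max: 12.8}
    - {index: 8, t_min: 11.6, t_max: 14.1}
    - {index: 9, t_min: 18.2, t_max: 21.8}
  exposure_onset: 0.0
  exposure_duration: 0.75
  unscheduled_void_rate: 0.08
  urine_flow_mean: 0.065
  volume_cv: 0.35
  overnight_gap_h: 7.5
  creatinine_rate_mean: 0.0625
  creatinine_subject_cv: 0.2
  creatinine_void_cv: 0.3
  baseline_subject_cv: 0.5
  ke_subject_cv: 0.2
analytes:
  DHN:
    lod: 0.3
    assay_cv: 0.094
    baseline_rate: 0.175
    dose_mean: 92.0
    dose_cv: 0.5
    ka: 2.0
    ke: 0.1050215
    fe: 1.0
  NAP1:
    lod: 0.1
    assay_cv: 0.14
    baseline_rate: 0.031
    dose_mean: 7.7
    dose_cv: 0.5
    ka: 2.0
    ke: 0.1117963
    fe: 1.0
  NAP2:
    lod: 0.1
    assay_cv: 0.14
    baseline_rate: 0.123
    dose_mean: 5.7
    dose_cv: 0.5
    ka: 2.0
    ke: 0.1332972
    fe: 1.0
  PYR1:
    lod: 0.02
    assay_cv: 0.14
    baseline_rate: 0.0034
    dose_mean: 0.31
    dose_cv: 0.5
    ka: 0.9
    ke: 0.0900187
    fe: 1.0
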