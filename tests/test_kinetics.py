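import math

import numpy as np
import pandas as pd
import pytest

from pahtk import (DecayLMM, DecayRecord, MixedModelSpec, build_decay_records,
                   derive_half_lives, fit_eq1_mixed, fit_from_samples,
                   locate_peak, summarize_time_to_peak, time_to_baseline)
from pahtk.kinetics import half_life_interval

from oracles import dense_decay_loglik, gls_beta, ols_line

LN2 = math.log(2)


def sample_set(values, times, baseline=None, t_base=-0.5):
    """One subject-session sample set over windows 3..9 (+ optional window 2)."""
    rows = []
    if baseline is not None:
        rows.append({"window_index": 2, "time_h": t_base, "t_mid_h": t_base - 2.0,
                     "DHN_ug_per_g": baseline, "included": 1})
    mids = [times[0]] + [0.5 * (a + b) for a, b in zip(times, times[1:])]
    for w, (c, t, m) in enumerate(zip(values, times, mids), start=3):
        rows.append({"window_index": w, "time_h": t, "t_mid_h": m,
                     "DHN_ug_per_g": c, "included": 1})
    df = pd.DataFrame(rows)
    df["subject_id"] = "S1"
    df["session_id"] = 1
    return df


class TestLocatePeak:
    TIMES = (2.0, 3.0, 5.2, 8.1, 11.2, 12.7, 20.1)

    def test_argmax_over_post_exposure_windows(self):
        s = sample_set((31, 134, 131, 86, 51, 46, 27), self.TIMES)
        peak = locate_peak(s, "DHN")
        assert (peak["t_peak"], peak["c_peak"]) == (3.0, 134)
        assert peak["window_index"] == 4

    def test_strictly_decreasing_series_peaks_first(self):
        s = sample_set((131, 86, 51, 46, 27, 20, 10), self.TIMES)
        assert locate_peak(s, "DHN")["window_index"] == 3

    def test_ties_break_to_the_earlier_time(self):
        s = sample_set((31, 134, 134, 86, 51, 46, 27), self.TIMES)
        assert locate_peak(s, "DHN")["t_peak"] == 3.0

    def test_excluded_samples_are_ineligible(self):
        s = sample_set((31, 134, 131, 86, 51, 46, 27), self.TIMES)
        s.loc[s["window_index"] == 4, "included"] = 0
        assert locate_peak(s, "DHN")["window_index"] == 5

    def test_no_eligible_samples_returns_none(self):
        s = sample_set((31, 134), self.TIMES[:2])
        s["included"] = 0
        assert locate_peak(s, "DHN") is None


class TestDecayRecords:
    def test_peak_record_at_t_zero_and_log_difference(self):
        s = sample_set((31.0, 134.0, 90.0), (2.0, 3.0, 5.2), baseline=3.3)
        records, dropped, peaks = build_decay_records(s, ["DHN"])
        by_t = {round(r.t, 6): r for r in records}
        assert 0.0 in by_t
        assert by_t[0.0].y == pytest.approx(math.log(134.0 - 3.3))
        assert len(peaks) == 1

    def test_log_difference_example(self):
        r = DecayRecord(subject_id="S1", session_id=1, biomarker="DHN",
                        t=17.1, C=27.1, C0=3.3)
        assert r.y == pytest.approx(math.log(23.8), abs=1e-6)
        assert r.y == pytest.approx(3.1697, abs=1e-4)

    def test_records_not_above_baseline_are_dropped(self):
        s = sample_set((31.0, 134.0, 3.3, 2.0), (2.0, 3.0, 5.2, 8.1), baseline=3.3)
        records, dropped, _ = build_decay_records(s, ["DHN"])
        assert dropped["records_nonpositive"] == 2  # C == C0 and C < C0
        assert all(r.C > r.C0 for r in records)

    def test_time_axis_uses_interval_midpoints(self):
        s = sample_set((31.0, 134.0, 90.0), (2.0, 3.0, 5.2), baseline=3.3)
        records, _, peaks = build_decay_records(s, ["DHN"])
        t_mid_peak = peaks.iloc[0]["t_mid_peak"]
        later = [r for r in records if r.t > 0][0]
        assert later.t == pytest.approx(0.5 * (3.0 + 5.2) - t_mid_peak)

    def test_set_without_baseline_is_excluded(self):
        s = sample_set((31.0, 134.0, 90.0), (2.0, 3.0, 5.2))  # no window 1/2
        records, dropped, _ = build_decay_records(s, ["DHN"])
        assert records == [] and dropped["sets_no_baseline"] == 1


def make_records(rng, n_participants=2, n_sessions=2, n_times=4,
                 biomarkers=("DHN",), lam=-0.12, sd=0.25, intercept_sd=0.0):
    records = []
    for p in range(n_participants):
        shift = intercept_sd * rng.standard_normal()
        for s in range(n_sessions):
            for b in biomarkers:
                for i in range(n_times):
                    t = 2.0 * i + rng.uniform(0, 0.5)
                    y = 4.0 + shift + lam * t + sd * rng.standard_normal()
                    records.append(DecayRecord(
                        subject_id=f"S{p+1}", session_id=s + 1, biomarker=b,
                        t=t, C=math.exp(y) + 1.0, C0=1.0))
    return records


def records_arrays(records):
    return (np.array([r.t for r in records]),
            np.array([r.y for r in records]),
            [r.biomarker for r in records],
            [r.subject_id for r in records],
            [str(r.session_id) for r in records])


class TestLikelihoodOracle:
    @pytest.mark.parametrize("seed,ar1", [(0, "order"), (1, "order"),
                                          (2, "continuous"), (3, "order")])
    def test_structured_equals_dense_likelihood(self, seed, ar1):
        rng = np.random.default_rng(seed)
        records = make_records(rng, biomarkers=("DHN", "PYR1")[: 1 + seed % 2])
        t, y, bio, part, sess = records_arrays(records)
        model = DecayLMM(t, y, bio, part, sess, spec=MixedModelSpec(ar1=ar1))
        sd_i, l21, sd_s, tau, sigma = 0.3, 0.1, 0.05, 0.2, 0.25
        phi = 0.4
        theta = [math.log(sd_i), l21, math.log(sd_s), math.log(tau),
                 math.log(sigma),
                 math.atanh(phi) if ar1 == "order" else math.log(phi / (1 - phi))]
        L = np.array([[sd_i, 0.0], [l21, sd_s]])
        G = L @ L.T
        levels = sorted(set(bio))
        beta = np.concatenate([rng.normal(4, 0.5, len(levels)),
                               rng.normal(-0.1, 0.02, len(levels))])
        beta_map = {b: (beta[k], beta[len(levels) + k])
                    for k, b in enumerate(levels)}
        ours = model.loglik_at(theta, beta)
        dense = dense_decay_loglik(t, y, bio, part, sess, beta_map,
                                   G, tau ** 2, sigma ** 2, phi, ar1=ar1)
        assert ours == pytest.approx(dense, abs=1e-6)

    def test_negative_phi_also_matches_dense(self):
        rng = np.random.default_rng(7)
        records = make_records(rng)
        t, y, bio, part, sess = records_arrays(records)
        model = DecayLMM(t, y, bio, part, sess)
        theta = [math.log(0.2), 0.0, math.log(0.05), math.log(0.1),
                 math.log(0.3), math.atanh(-0.5)]
        beta_map = {"DHN": (4.0, -0.12)}
        dense = dense_decay_loglik(t, y, bio, part, sess, beta_map,
                                   np.diag([0.04, 0.0025]), 0.01, 0.09, -0.5)
        assert model.loglik_at(theta, [4.0, -0.12]) == pytest.approx(dense, abs=1e-6)


class TestReductions:
    def test_zero_variances_and_phi_reduce_to_ols(self):
        rng = np.random.default_rng(5)
        records = make_records(rng, n_participants=3)
        t, y, bio, part, sess = records_arrays(records)
        model = DecayLMM(t, y, bio, part, sess)
        tiny = math.log(1e-8)
        beta, _ = model.profile_beta([tiny, 0.0, tiny, tiny, math.log(0.3), 0.0])
        icept, slope = ols_line(t, y)
        assert beta[1] == pytest.approx(slope, abs=1e-8)
        assert beta[0] == pytest.approx(icept, abs=1e-8)

    def test_fixed_phi_reduces_to_closed_form_gls(self):
        # one series, no random effects: AR(1) GLS in closed form
        rng = np.random.default_rng(6)
        records = make_records(rng, n_participants=1, n_sessions=1, n_times=8)
        t, y, bio, part, sess = records_arrays(records)
        model = DecayLMM(t, y, bio, part, sess)
        phi, sigma = 0.6, 0.3
        tiny = math.log(1e-8)
        beta, _ = model.profile_beta(
            [tiny, 0.0, tiny, tiny, math.log(sigma), math.atanh(phi)])
        order = np.argsort(t)
        X = np.column_stack([np.ones(len(t)), t[order]])
        V = sigma ** 2 * phi ** np.abs(np.subtract.outer(range(8), range(8)))
        expected = gls_beta(X, y[order], V)
        assert np.allclose(beta, expected, atol=1e-8)

    def test_compound_symmetry_matches_statsmodels(self):
        # phi = 0, random intercept only: cross-check against an independent
        # REML implementation
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        records = make_records(rng, n_participants=8, n_sessions=1, n_times=6,
                               intercept_sd=0.4)
        t, y, bio, part, sess = records_arrays(records)
        spec = MixedModelSpec(ar1="none", random_slope=False,
                              session_intercept=False)
        res = DecayLMM(t, y, bio, part, sess, spec=spec).fit()
        X = sm.add_constant(t)
        sm_res = sm.MixedLM(y, X, groups=np.array(part)).fit(reml=True)
        assert res.beta[0] == pytest.approx(sm_res.params[0], rel=1e-4, abs=1e-5)
        assert res.beta[1] == pytest.approx(sm_res.params[1], rel=1e-4, abs=1e-6)
        assert res.varcomps["residual_sd"] ** 2 == pytest.approx(
            sm_res.scale, rel=0.01)
        assert res.varcomps["participant_intercept_sd"] ** 2 == pytest.approx(
            float(np.asarray(sm_res.cov_re)[0, 0]), rel=0.02, abs=1e-4)


class TestFit:
    def test_exact_exponential_recovered_to_machine_precision(self):
        records = [DecayRecord(subject_id="S1", session_id=1, biomarker="DHN",
                               t=t, C=100.0 * math.exp(-0.1 * t), C0=0.0)
                   for t in np.arange(0.0, 13.0, 2.0)]
        fit = fit_eq1_mixed(records)
        k = fit.biomarkers["DHN"]
        assert k.lam == pytest.approx(-0.1, abs=1e-8)
        assert k.half_life == pytest.approx(LN2 / 0.1, rel=1e-6)
        assert fit.varcomps["residual_sd"] < 1e-3

    def test_rescaling_concentrations_leaves_slopes_unchanged(self, samples, analytes):
        fit1, _, _ = fit_from_samples(samples, ["DHN", "NAP2"])
        scaled = samples.copy()
        for name in ("DHN", "NAP2"):
            scaled[f"{name}_ug_per_g"] = 3.7 * scaled[f"{name}_ug_per_g"]
        fit2, _, _ = fit_from_samples(scaled, ["DHN", "NAP2"])
        for name in ("DHN", "NAP2"):
            assert fit2.biomarkers[name].lam == pytest.approx(
                fit1.biomarkers[name].lam, rel=1e-4)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            fit_eq1_mixed([DecayRecord("S1", 1, "DHN", 0.0, 10.0, 1.0)] * 3)


class TestHalfLives:
    def test_round_trip_through_lambda(self):
        for hl in (1.0, 5.2, 6.6, 7.7):
            lam = -LN2 / hl
            assert half_life_interval(lam, lam, lam)[0] == pytest.approx(hl)

    def test_printed_slope_gives_printed_half_life(self):
        hl, _, valid = half_life_interval(-0.10503, -0.10503, -0.10503)
        assert valid and hl == pytest.approx(6.6, abs=0.01)

    def test_ci_endpoints_transform_monotonically(self):
        hl, (lo, hi), valid = half_life_interval(-0.10503, -0.12836, -0.08061)
        assert valid
        assert lo == pytest.approx(5.4, abs=0.05)
        assert hi == pytest.approx(8.6, abs=0.05)
        assert lo < hl < hi

    def test_nonnegative_slope_flagged_invalid(self):
        hl, _, valid = half_life_interval(0.01, -0.01, 0.03)
        assert not valid and math.isnan(hl)

    def test_derive_half_lives_exposes_fit_values(self):
        records = [DecayRecord("S1", 1, "DHN", t, 50 * math.exp(-0.2 * t), 0.0)
                   for t in range(6)]
        fit = fit_eq1_mixed(records)
        hl, (lo, hi) = derive_half_lives(fit)["DHN"]
        assert hl == pytest.approx(LN2 / 0.2, rel=1e-6)
        assert lo <= hl <= hi


class TestTimeToBaseline:
    def test_no_excess_means_zero_time(self):
        res = time_to_baseline(5.0, 5.0, 6.6)
        assert res.n_halvings == 0.0 and res.hours == 0.0

    def test_five_half_lives_of_6_6_hours(self):
        res = time_to_baseline(32.0, 1.0, 6.6)
        assert res.n_halvings == pytest.approx(5.0)
        assert res.hours == pytest.approx(33.0)

    def test_peak_to_baseline_ratio_from_reported_medians(self):
        res = time_to_baseline(134.15, 3.32, 6.6)
        assert res.n_halvings == pytest.approx(5.34, abs=0.01)
        assert res.hours == pytest.approx(35.3, abs=0.1)
        assert res.hours_rounded_n == pytest.approx(5 * 6.6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            time_to_baseline(1.0, 2.0, 6.6)
        with pytest.raises(ValueError):
            time_to_baseline(2.0, 1.0, 0.0)


class TestTimeToPeakSummary:
    def test_median_and_range(self):
        peaks = pd.DataFrame({"biomarker": "DHN", "t_peak": [2.9, 3.3, 3.5]})
        out = summarize_time_to_peak(peaks)
        row = out.iloc[0]
        assert row["median_h"] == 3.3
        assert (row["min_h"], row["max_h"]) == (2.9, 3.5)

    def test_single_set_collapses(self):
        peaks = pd.DataFrame({"biomarker": ["PYR1"], "t_peak": [5.3]})
        row = summarize_time_to_peak(peaks).iloc[0]
        assert row["median_h"] == row["min_h"] == row["max_h"] == 5.3
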