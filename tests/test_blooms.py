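"""Bloom-onset rule, covariate standardization, mixed logit, AIC selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from bloomkit import blooms


def brute_force_onsets(b, rule, ci_thr):
    """Literal re-application of the rule, sample by sample."""
    out = []
    for i in range(1, len(b)):
        growth = b[i] > rule.factor * b[i - 1] if b[i - 1] > 0 else b[i] > 0
        over_abs = b[i] > rule.abs_threshold
        over_ci = b[i] > ci_thr
        over = {"fixed": over_abs, "ci": over_ci,
                "either": over_abs or over_ci,
                "both": over_abs and over_ci}[rule.mode]
        out.append(int(growth and over))
    return np.array([0] + out)


class TestDetectOnsets:
    def test_single_onset_with_class(self):
        rule = blooms.BloomRule(factor=3.0, abs_threshold=4.0, mode="fixed")
        flags, events = blooms.detect_bloom_onsets(
            [6.0, 6.0, 19.0, 21.0], rule)
        assert flags.tolist() == [0, 0, 1, 0]
        assert len(events) == 1
        assert events[0].onset_index == 2
        assert events[0].magnitude_class == "8-20"
        # the magnitude classes partition at 4, 8 and 20 g DM m⁻³,
        # with 20 itself in the largest class
        assert blooms.detect_bloom_onsets([6.0, 20.0], rule)[1][0] \
            .magnitude_class == ">=20"

    def test_constant_series_no_onsets(self):
        rule = blooms.BloomRule(mode="fixed")
        flags, events = blooms.detect_bloom_onsets([5.0] * 6, rule)
        assert flags.sum() == 0 and not events

    def test_threshold_conjunction(self):
        # 250% increase but threshold unmet -> no onset
        rule = blooms.BloomRule(factor=3.0, abs_threshold=4.0, mode="fixed")
        flags, _ = blooms.detect_bloom_onsets([1.0, 3.5], rule)
        assert flags.sum() == 0

    def test_rise_from_zero_counts_when_over_threshold(self):
        rule = blooms.BloomRule(mode="fixed")
        flags, _ = blooms.detect_bloom_onsets([0.0, 5.0], rule)
        assert flags.tolist() == [0, 1]

    @pytest.mark.parametrize("mode", ["fixed", "ci", "either", "both"])
    def test_matches_brute_force_on_fuzzed_series(self, mode, rng):
        rule = blooms.BloomRule(mode=mode)
        for _ in range(50):
            b = rng.lognormal(1.0, 1.2, size=rng.integers(5, 40))
            ci = blooms.lake_ci_threshold(b, rule.ci_level)
            flags, events = blooms.detect_bloom_onsets(b, rule)
            assert np.array_equal(flags, brute_force_onsets(b, rule, ci))
            assert all(flags[e.onset_index] == 1 for e in events)

    def test_recall_on_noise_free_synthetic_blooms(self, noise_free_lake):
        # injected blooms >= 3x background and above threshold: perfect
        # recall, zero false positives
        _, ts, truth = noise_free_lake
        rule = blooms.BloomRule(factor=3.0, abs_threshold=4.0, mode="fixed")
        flags, _ = blooms.detect_bloom_onsets(
            ts.data["total_rotifer_biomass"].to_numpy(), rule)
        assert set(np.flatnonzero(flags)) == set(truth.bloom_onset_weeks.tolist())


class TestLakeCIThreshold:
    def test_zero_variance(self):
        assert blooms.lake_ci_threshold([3.0, 3.0, 3.0]) == 3.0

    def test_closed_form(self):
        # mean 4 + 1.6449 * sd 2 / sqrt(3)
        expected = 4 + 1.6449 * 2 / math.sqrt(3)
        assert blooms.lake_ci_threshold([2.0, 4.0, 6.0], 0.90) == \
            pytest.approx(expected, abs=1e-3)

    def test_monotone_in_level(self):
        x = [2.0, 4.0, 6.0, 8.0]
        assert blooms.lake_ci_threshold(x, 0.95) > blooms.lake_ci_threshold(x, 0.90)

    def test_insufficient_data(self):
        with pytest.raises(blooms.InsufficientDataError):
            blooms.lake_ci_threshold([1.0, 2.0])


class TestStandardize:
    def test_pooled_zscore(self, seven_lakes):
        _, ds, _ = seven_lakes
        df = ds.to_frame()
        out = blooms.standardize_covariates(df, ["salinity", "chla_ug_l"])
        for v in ("salinity", "chla_ug_l"):
            assert out[v].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[v].std(ddof=1) == pytest.approx(1.0)

    def test_range_transform(self):
        df = pd.DataFrame({"x": [1.0, 3.0, 5.0]})
        out = blooms.standardize_covariates(df, ["x"], mode="range")
        assert out["x"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            blooms.standardize_covariates(df, ["x"])


def _simulate_logit_corpus(seed, beta_sal=-1.5, sigma=0.5, n_lakes=7, n_obs=60):
    rng = np.random.default_rng(seed)
    rows = []
    for lake in range(n_lakes):
        u = rng.normal(0.0, sigma)
        sal = rng.normal(0.0, 1.0, n_obs)
        chla = rng.normal(0.0, 1.0, n_obs)
        p = expit(-1.0 + beta_sal * sal + u)
        y = (rng.random(n_obs) < p).astype(int)
        for i in range(n_obs):
            rows.append({"lake_id": f"L{lake}", "salinity": sal[i],
                         "chla": chla[i], "onset": y[i]})
    return pd.DataFrame(rows)


class TestMixedLogit:
    def test_sigma_zero_reduces_to_plain_logit(self):
        import statsmodels.api as sm
        df = _simulate_logit_corpus(0)
        fit = blooms.fit_bloom_logit(df, "onset", ["salinity", "chla"],
                                     group=None)
        x = sm.add_constant(df[["salinity", "chla"]])
        ref = sm.Logit(df["onset"], x).fit(disp=0)
        assert np.allclose(fit.params.to_numpy(), ref.params.to_numpy(),
                           atol=1e-6)

    def test_negative_salinity_effect_detected(self):
        df = _simulate_logit_corpus(42)
        fit = blooms.fit_bloom_logit(df, "onset", ["salinity", "chla"])
        assert fit.converged
        assert fit.params["salinity"] < 0
        assert abs(fit.zvalues["salinity"]) > 2

    def test_aic_definition(self):
        df = _simulate_logit_corpus(1)
        fit = blooms.fit_bloom_logit(df, "onset", ["salinity"])
        # k = intercept + salinity + random-intercept sd
        assert fit.k == 3
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: R lme4 glmer with adaptive quadrature."""
        import json
        import shutil
        import subprocess
        df = _simulate_logit_corpus(42)
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        csv = tmp_path / "mix.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4)); library(jsonlite)\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(onset ~ salinity + chla + (1|lake_id), data=d,"
            " family=binomial, nAGQ=20)\n"
            "cat(toJSON(list(beta=unname(fixef(m)),"
            " sigma=unname(sqrt(unlist(VarCorr(m)))),"
            " loglik=as.numeric(logLik(m))), digits=10))\n")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        ref = json.loads(out.stdout)
        fit = blooms.fit_bloom_logit(df, "onset", ["salinity", "chla"])
        assert np.allclose(fit.params.to_numpy(), ref["beta"], atol=2e-3)
        assert fit.sigma_lake == pytest.approx(ref["sigma"][0], abs=2e-3)
        assert fit.loglik == pytest.approx(ref["loglik"][0], abs=1e-3)

    def test_null_type_one_behaviour(self):
        # no true effects: |z| < 2 for all predictors in most seeded runs
        calm = 0
        runs = 30
        for seed in range(runs):
            df = _simulate_logit_corpus(1000 + seed, beta_sal=0.0)
            fit = blooms.fit_bloom_logit(df, "onset", ["salinity", "chla"])
            if (fit.zvalues[["salinity", "chla"]].abs() < 2).all():
                calm += 1
        assert calm >= 0.8 * runs


class TestSelectModelAIC:
    def test_table_has_all_subsets(self):
        df = _simulate_logit_corpus(3)
        _, table = blooms.select_model_aic(df, "onset", ["salinity", "chla"])
        assert len(table) == 4  # 2^2

    def test_true_predictor_selected(self):
        hits = 0
        for seed in range(10):
            df = _simulate_logit_corpus(200 + seed, beta_sal=-1.5)
            best, _ = blooms.select_model_aic(df, "onset",
                                              ["salinity", "chla"])
            hits += "salinity" in best.predictors
        assert hits >= 9

    def test_reproducible_ranking(self):
        df = _simulate_logit_corpus(4)
        _, t1 = blooms.select_model_aic(df, "onset", ["salinity", "chla"])
        _, t2 = blooms.select_model_aic(df, "onset", ["salinity", "chla"])
        pd.testing.assert_frame_equal(t1, t2)


class TestPrebloomContrast:
    def test_identical_values_give_null_result(self):
        df = pd.DataFrame({"filamentous_frac": [0.3] * 6,
                           "lake_id": ["A"] * 6})
        events = [blooms.BloomEvent("A", 2, 10.0, "8-20"),
                  blooms.BloomEvent("A", 4, 10.0, "8-20")]
        res = blooms.prebloom_contrast(df, events, "filamentous_frac")
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_constant_shift_degenerate(self):
        df = pd.DataFrame({"v": [0.1, 0.3, 0.1, 0.3, 0.1, 0.3],
                           "lake_id": ["A"] * 6})
        events = [blooms.BloomEvent("A", 1, 10.0, "8-20"),
                  blooms.BloomEvent("A", 3, 10.0, "8-20"),
                  blooms.BloomEvent("A", 5, 10.0, "8-20")]
        res = blooms.prebloom_contrast(df, events, "v")
        assert res.degenerate and res.p_value == 0.0
        assert res.mean_difference == pytest.approx(0.2)

    def test_matches_textbook_paired_t(self):
        from scipy import stats
        pre = [0.20, 0.35, 0.15]
        on = [0.40, 0.50, 0.45]
        df = pd.DataFrame({
            "v": [pre[0], on[0], pre[1], on[1], pre[2], on[2]],
            "lake_id": ["A"] * 6})
        events = [blooms.BloomEvent("A", i, 10.0, "8-20") for i in (1, 3, 5)]
        res = blooms.prebloom_contrast(df, events, "v")
        t_ref, p_ref = stats.ttest_rel(on, pre)
        assert res.t_statistic == pytest.approx(t_ref)
        assert res.p_value == pytest.approx(p_ref)


class TestBloomFrequency:
    def test_inverse_arithmetic(self):
        # 36 events over 187.2 monitored months -> one bloom per 5.2 months
        res = blooms.bloom_frequency(187.2, 36)
        assert res.months_per_bloom == pytest.approx(5.2)

    def test_single_event_single_month(self):
        assert blooms.bloom_frequency(1.0, 1).months_per_bloom == 1.0

    def test_proportionality(self):
        a = blooms.bloom_frequency(100.0, 10)
        b = blooms.bloom_frequency(200.0, 10)
        assert b.months_per_bloom == pytest.approx(2 * a.months_per_bloom)

    def test_zero_events_flagged_infinite(self):
        res = blooms.bloom_frequency(12.0, 0)
        assert res.no_events and math.isinf(res.months_per_bloom)
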