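"""Screening tests, mixed determinants models, elimination, R^2, CV."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cdvar
from cdvar import determinants as det
from cdvar.synthetic import GeneratorConfig


class TestKruskalWallis:
    def test_rank_sum_formula_example(self):
        # {1,2,3} vs {4,5,6}: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) = 3.857
        h, p = det.kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, rel=1e-9)
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_equal_constant_groups(self):
        h, p = det.kruskal_wallis([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert h == 0.0
        assert p == 1.0

    def test_null_calibration_under_label_shuffles(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 60)
        ps = []
        for _ in range(300):
            labels = rng.permutation(np.repeat(["a", "b", "c"], 20))
            ps.append(det.kruskal_wallis(x, labels)[1])
        # p-values approximately uniform: rejection rate near alpha
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.035)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            det.kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestTrendTest:
    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 400
        for _ in range(reps):
            age = rng.uniform(31, 84, 120)
            x = rng.normal(0, 1, 120)
            y = 0.01 * age + rng.normal(0, 0.5, 120)
            _, p = det.trend_test(y, x, age)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_slope_recovery_with_injected_effect(self):
        rng = np.random.default_rng(7)
        covered = 0
        reps = 100
        for _ in range(reps):
            age = rng.uniform(31, 84, 250)
            x = rng.uniform(0, 100, 250)
            y = 0.01 * x + 0.005 * age + rng.normal(0, 0.3, 250)
            slope, p = det.trend_test(y, x, age)
            se = 0.3 / (np.std(x) * math.sqrt(250))
            covered += abs(slope - 0.01) < 1.96 * se * 1.1
        assert covered / reps >= 0.90

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            det.trend_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [40.0, 50.0, 60.0])

    def test_predictor_collinear_with_age_rejected(self):
        age = np.array([40.0, 50.0, 60.0, 70.0])
        with pytest.raises(ValueError):
            det.trend_test([1.0, 2.0, 3.0, 4.0], 2 * age + 1, age)


class TestPercentChange:
    @given(beta=st.floats(min_value=-1.5, max_value=1.5))
    @settings(max_examples=100, derandomize=True)
    def test_inverse_identity(self, beta):
        """ln(1 + pct/100) recovers beta to 1e-12."""
        pct = (math.exp(beta) - 1) * 100
        assert math.log1p(pct / 100) == pytest.approx(beta, abs=1e-12)


@pytest.fixture(scope="module")
def calibrated_frame():
    """A larger cohort so every injected effect is comfortably powered."""
    cfg = GeneratorConfig(n_participants=900, seed=21)
    cohort = cdvar.generate_cohort(cfg)
    samples = cdvar.generate_samples(cohort, cfg)
    processed = cdvar.process_samples(samples)
    geo = cdvar.generate_geography(cohort, cfg)
    cont = cdvar.generate_contaminant_table(cfg)
    ffq = cdvar.generate_ffq(cohort, cont, cfg)
    profiles = cdvar.build_exposure_profiles(cohort, geo, ffq, cont)
    return det.build_model_frame(processed, cohort, profiles)


class TestFitMixed:
    def test_recovers_creatinine_percent_change(self, calibrated_frame):
        # generated with +15% per 0.1 g/L creatinine
        fit = det.fit_mixed(calibrated_frame, det.DEFAULT_TERMS, compute_r2=False)
        est = fit.pct_change.loc["creatinine_per01", "estimate"]
        assert est == pytest.approx(15.0, abs=2.0)

    def test_null_term_ci_covers_zero(self, calibrated_frame):
        # dietary cadmium carries no injected effect
        fit = det.fit_mixed(calibrated_frame, det.DEFAULT_TERMS, compute_r2=False)
        row = fit.pct_change.loc["dietary_cd"]
        assert row["low"] < 0 < row["high"]

    def test_null_term_coverage_over_replicates(self):
        hits, reps = 0, 30
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            n = 150
            g = np.repeat(np.arange(n), 2)
            x = rng.normal(0, 1, n)[g]
            noise = rng.normal(0, 1, n)[g]  # beta = 0 injected
            y = 0.5 * x + rng.normal(0, 0.5, n)[g] + rng.normal(0, 0.5, 2 * n)
            df = pd.DataFrame(
                {"participant_id": g, "log_cd": y, "x": x, "z": noise}
            )
            fit = det.fit_mixed(df, ["x", "z"], compute_r2=False)
            row = fit.pct_change.loc["z"]
            hits += row["low"] < 0 < row["high"]
        assert hits / reps >= 0.85   # ~95% coverage, binomial slack

    def test_single_sample_per_person_reduces_to_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 200
        x = rng.normal(0, 1, n)
        y = 0.4 * x + rng.normal(0, 0.8, n)
        df = pd.DataFrame({"participant_id": np.arange(n), "log_cd": y, "x": x})
        fit = det.fit_mixed(df, ["x"], compute_r2=False)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.beta["x"] == pytest.approx(ols.params[1], abs=1e-4)

    def test_rank_deficient_design_names_term(self, calibrated_frame):
        df = calibrated_frame.copy()
        df["dup"] = df["age0"] * 2.0
        with pytest.raises(ValueError, match="dup"):
            det.fit_mixed(df, ["age0", "dup"], compute_r2=False)

    def test_age_rescaling_changes_only_intercept(self, calibrated_frame):
        terms = ["creatinine_per01", "age0", "parity"]
        fit0 = det.fit_mixed(calibrated_frame, terms)
        shifted = calibrated_frame.copy()
        shifted["age0"] = shifted["age0"] + 31.0   # un-rescaled coding
        fit1 = det.fit_mixed(shifted, terms)
        for t in terms:
            assert fit1.beta[t] == pytest.approx(fit0.beta[t], abs=1e-5)
        assert fit1.r2 == pytest.approx(fit0.r2, abs=1e-5)
        assert fit1.beta["intercept"] != pytest.approx(fit0.beta["intercept"], abs=1e-3)


class TestBackwardElimination:
    def test_powered_terms_survive(self, calibrated_frame):
        fit = det.backward_eliminate(
            calibrated_frame, det.DEFAULT_TERMS, det.FORCED_TERMS
        )
        for t in ("creatinine_per01", "age0", "pack_years", "parity", "alcohol_category"):
            assert t in fit.terms

    def test_forced_terms_always_retained(self, calibrated_frame):
        # environmental/dietary metrics carry no injected effect yet must stay
        fit = det.backward_eliminate(
            calibrated_frame, det.DEFAULT_TERMS, det.FORCED_TERMS
        )
        assert set(det.FORCED_TERMS) <= set(fit.terms)

    def test_pure_noise_covariate_removed(self, calibrated_frame):
        removed = 0
        for r in range(10):
            df = calibrated_frame.copy()
            rng = np.random.default_rng(300 + r)
            noise = pd.Series(
                rng.normal(0, 1, df["participant_id"].nunique()),
                index=df["participant_id"].unique(),
            )
            df["noise_q"] = df["participant_id"].map(noise)
            fit = det.backward_eliminate(
                df, det.DEFAULT_TERMS + ["noise_q"], det.FORCED_TERMS
            )
            removed += "noise_q" not in fit.terms
        assert removed >= 9

    def test_threshold_one_keeps_full_model(self, calibrated_frame):
        fit = det.backward_eliminate(
            calibrated_frame, det.DEFAULT_TERMS, det.FORCED_TERMS, threshold=1.0
        )
        assert fit.terms == det.DEFAULT_TERMS

    def test_all_surviving_nonforced_terms_significant(self, calibrated_frame):
        # the loop's contract: it stops exactly when every non-forced
        # term sits below the threshold
        fit = det.backward_eliminate(
            calibrated_frame, det.DEFAULT_TERMS, det.FORCED_TERMS, threshold=0.1
        )
        surviving = [t for t in fit.terms if t not in det.FORCED_TERMS]
        assert all(fit.p[t] < 0.1 for t in surviving)
        n_removed = len(det.DEFAULT_TERMS) - len(fit.terms)
        assert n_removed <= len(det.DEFAULT_TERMS) - len(det.FORCED_TERMS)

    def test_forced_not_subset_rejected(self, calibrated_frame):
        with pytest.raises(ValueError):
            det.backward_eliminate(calibrated_frame, ["age0"], ["not_a_term"])


class TestCumulativeR2:
    def test_monotone_nondecreasing(self, calibrated_frame):
        r2 = det.cumulative_r2(calibrated_frame, det.DEFAULT_TERMS)
        diffs = np.diff(np.concatenate([[0.0], r2.to_numpy()]))
        assert (diffs >= -1e-6).all()

    def test_final_r2_in_generator_truth_range(self, calibrated_frame):
        # variance accounting of the default effects puts the explained
        # share of ln U-Cd in the low 40s of percent
        r2 = det.cumulative_r2(calibrated_frame, det.DEFAULT_TERMS)
        assert 0.33 <= r2.iloc[-1] <= 0.50


class TestCrossValidation:
    def test_folds_partition_participants(self, calibrated_frame):
        sub = calibrated_frame.dropna(subset=det.DEFAULT_TERMS)
        cv = det.crossvalidate_10fold(sub, ["creatinine_per01", "age0"], seed=3)
        assert len(cv.r2_by_fold) == 10
        assert cv.coefficients.shape == (10, 2)

    def test_homogeneous_data_has_stable_coefficients(self, calibrated_frame):
        sub = calibrated_frame.dropna(subset=det.DEFAULT_TERMS)
        cv = det.crossvalidate_10fold(
            sub, ["creatinine_per01", "age0", "pack_years"], seed=3
        )
        # the well-powered dilution term moves by well under +/-10%
        # across folds; weaker terms wobble more with their larger SEs
        full = det.fit_mixed(sub, ["creatinine_per01", "age0", "pack_years"],
                             compute_r2=False)
        ref = full.beta["creatinine_per01"]
        dev = (cv.coefficients["creatinine_per01"] - ref).abs() / abs(ref)
        assert dev.max() < 0.10
        lo, hi = cv.r2_range
        assert hi - lo < 0.06

    def test_too_few_participants_rejected(self):
        df = pd.DataFrame(
            {
                "participant_id": np.arange(5),
                "log_cd": np.random.default_rng(0).normal(size=5),
                "x": np.arange(5.0),
            }
        )
        with pytest.raises(ValueError):
            det.crossvalidate_10fold(df, ["x"], seed=0)


class TestQuitDecay:
    def test_offset_rule_shifts_only_the_intercept(self, calibrated_frame):
        a = det.quit_decay(calibrated_frame, offset_years=3.0)
        b = det.quit_decay(calibrated_frame, offset_years=0.0)
        assert a["pct_change_per_year"] == pytest.approx(
            b["pct_change_per_year"], abs=1e-6
        )
        assert a["p"] == pytest.approx(b["p"], abs=1e-6)

    def test_recovers_injected_decay(self):
        # the generator injects a -1.5%/year decay among former smokers;
        # the 95% CI should cover it in most replicates
        covered, negative = 0, 0
        seeds = (33, 34, 35, 36, 37)
        for seed in seeds:
            cfg = GeneratorConfig(n_participants=1200, seed=seed)
            cohort = cdvar.generate_cohort(cfg)
            samples = cdvar.generate_samples(cohort, cfg)
            frame = cdvar.process_samples(samples).merge(cohort, on="participant_id")
            frame["creatinine_per01"] = frame["creatinine_gL"] * 10
            frame["age0"] = frame["age"] - frame["age"].min()
            res = det.quit_decay(frame)
            covered += res["ci95"][0] < -1.5 < res["ci95"][1]
            negative += res["pct_change_per_year"] < 0
        assert covered >= 4
        assert negative >= 4

    def test_empty_subset_rejected(self, calibrated_frame):
        never_only = calibrated_frame[calibrated_frame["smoking_status"] == "never"]
        with pytest.raises(ValueError):
            det.quit_decay(never_only)


class TestScreening:
    def test_alcohol_single_ordinal_slope(self, calibrated_frame):
        # the ordinal {0,1,2} coding yields one slope; injected effect is
        # -16% per category so the trend is strongly negative
        first = calibrated_frame[calibrated_frame["occasion"] == 1]
        res = det.screen_variable(first, "alcohol_category")
        assert len(res.categories) == 3
        assert res.trend_p < 0.01
        slope, _ = det.trend_test(
            first["log_cd"], first["alcohol_category"], first["age"]
        )
        assert slope < 0

    def test_screen_age_variable(self, calibrated_frame):
        first = calibrated_frame[calibrated_frame["occasion"] == 1]
        res = det.screen_variable(first, "age", bins=[31, 40, 50, 60, 85])
        assert sum(res.n_by_category) == len(first.dropna(subset=["age"]))
        assert res.trend_p < 0.05   # +1.4%/year injected
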