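"""GEE fitting, effective tests, Bonferroni, sensitivity suite and
cohort description."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famine_metabosig.exposure import classify_cohort
from famine_metabosig.mwas import (
    bonferroni_threshold,
    describe_cohort,
    effective_tests,
    fit_gee,
    run_mwas,
    sensitivity_suite,
)
from famine_metabosig.pipeline import preprocess_matrix
from famine_metabosig.preprocessing import LOG_SCALED, BiomarkerMatrix
from famine_metabosig.synthetic import generate_study

from conftest import small_config
from gee_oracle import gee_exchangeable_oracle


def _design(X: np.ndarray, names=None) -> pd.DataFrame:
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


class TestFitGee:
    def test_cluster_size_one_equals_robust_ols(self, rng):
        """With singleton clusters GEE degenerates to OLS with HC SEs."""
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + rng.normal(size=n)
        res = fit_gee(y, _design(X), np.arange(n))
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res["beta"], ols.params, atol=1e-8)
        hc0 = sm.OLS(y, X).fit(cov_type="HC0")
        np.testing.assert_allclose(res["se"], hc0.bse, rtol=1e-6)

    def test_perfect_fit(self):
        x = np.arange(1.0, 9.0)
        y = 2.0 * x
        X = np.column_stack([np.ones(8), x])
        res = fit_gee(y, _design(X), np.repeat([1, 2, 3, 4], 2))
        assert res["beta"].iloc[1] == pytest.approx(2.0, abs=1e-10)
        assert res["se"].iloc[1] == pytest.approx(0.0, abs=1e-8)

    def test_six_row_fixture_matches_oracle(self):
        """2 sibships of 3 against the independently coded IRLS oracle."""
        y = np.array([1.2, 0.8, 1.0, -0.3, 0.1, -0.5])
        X = np.column_stack([np.ones(6), [1, 0, 1, 0, 1, 0]])
        cl = np.array([1, 1, 1, 2, 2, 2])
        beta, se, _ = gee_exchangeable_oracle(y, X, cl)
        res = fit_gee(y, _design(X), cl)
        np.testing.assert_allclose(res["beta"], beta, atol=1e-6)
        np.testing.assert_allclose(res["se"], se, atol=1e-6)

    def test_oracle_agreement_with_sibling_pairs(self, rng):
        n = 120
        cl = np.repeat(np.arange(60), 2)
        X = np.column_stack(
            [np.ones(n), rng.binomial(1, 0.5, n), rng.normal(size=n)]
        )
        y = X @ [0.2, 0.3, -0.1] + 0.6 * rng.normal(size=60)[cl] + rng.normal(size=n)
        beta, se, _ = gee_exchangeable_oracle(y, X, cl)
        res = fit_gee(y, _design(X), cl)
        np.testing.assert_allclose(res["beta"], beta, atol=1e-6)
        np.testing.assert_allclose(res["se"], se, atol=1e-6)

    def test_rank_deficient_design_raises(self, rng):
        n = 20
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_gee(rng.normal(size=n), _design(X, ["c", "x", "x2"]), np.arange(n))

    def test_constant_outcome_raises(self):
        X = np.ones((10, 1))
        with pytest.raises(ValueError, match="constant"):
            fit_gee(np.ones(10), _design(X), np.arange(10))

    def test_robust_se_nonnegative_and_coverage(self, rng):
        """95% CI covers the truth at ~nominal rate over simulations."""
        truth = 0.4
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            n = 60
            cl = np.repeat(np.arange(30), 2)
            e = rng.binomial(1, 0.5, 30)[cl]
            X = np.column_stack([np.ones(n), e])
            y = truth * e + 0.5 * rng.normal(size=30)[cl] + rng.normal(size=n)
            res = fit_gee(y, _design(X, ["c", "e"]), cl)
            assert (res["se"] >= 0).all()
            covered += res.loc["e", "ci_low"] <= truth <= res.loc["e", "ci_high"]
        # binomial 3-sigma band around 0.95 (robust SEs are slightly
        # anticonservative at 30 clusters)
        assert 0.90 <= covered / n_sim <= 0.985


class TestEffectiveTests:
    def test_exactly_orthogonal_panel(self, rng):
        """Sample-uncorrelated columns: k = ceil(0.95 * p)."""
        n, p = 200, 40
        a = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        q, _ = np.linalg.qr(a)
        cols = q[:, 1:]  # exactly orthonormal and mean-zero
        vals = pd.DataFrame(cols, columns=[f"b{i}" for i in range(p)])
        m = BiomarkerMatrix(vals / vals.std(ddof=1), state=LOG_SCALED)
        assert effective_tests(m) == int(np.ceil(0.95 * p))

    def test_rank_one_matrix(self, rng):
        base = rng.normal(size=50)
        vals = pd.DataFrame({f"b{i}": base * (i + 1) for i in range(6)})
        m = BiomarkerMatrix(vals, state=LOG_SCALED)
        assert effective_tests(m) == 1

    def test_monotone_in_correlation(self, rng):
        n, p = 300, 20
        ks = []
        for rho in (0.2, 0.5, 0.8):
            u = rng.normal(size=(n, 1))
            x = np.sqrt(rho) * u + np.sqrt(1 - rho) * rng.normal(size=(n, p))
            m = BiomarkerMatrix(
                pd.DataFrame(x, columns=[f"b{i}" for i in range(p)]),
                state=LOG_SCALED,
            )
            ks.append(effective_tests(m))
        assert ks[0] >= ks[1] >= ks[2]

    def test_missing_values_raise(self):
        vals = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            effective_tests(BiomarkerMatrix(vals, state=LOG_SCALED))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [(0.05, 14, 0.05 / 14), (0.05, 1, 0.05), (0.05, 154, 0.05 / 154)],
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_strictly_decreasing_in_m(self):
        ts = [bonferroni_threshold(0.05, m) for m in range(1, 30)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestRunMwas:
    def test_single_biomarker_consistency(self, small_analysis):
        cohort, matrix, _ = small_analysis
        sub = BiomarkerMatrix(
            matrix.values[["tyrosine"]],
            matrix.below_lod[["tyrosine"]],
            LOG_SCALED,
        )
        table = run_mwas(sub, cohort, m_eff=2)
        assert len(table) == 1
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "any_exposure": cohort["any_exposure"].astype(float).to_numpy(),
                "age": cohort["age"].to_numpy(),
                "sex": cohort["sex"].astype(float).to_numpy(),
                "medication": cohort["medication"].astype(float).to_numpy(),
            }
        )
        direct = fit_gee(
            matrix.values["tyrosine"], design, cohort["sibship_id"]
        ).loc["any_exposure"]
        assert table["beta"].iloc[0] == pytest.approx(direct["beta"], abs=1e-10)
        assert table["p"].iloc[0] == pytest.approx(direct["p"], abs=1e-10)

    def test_row_order_invariance(self, small_analysis):
        cohort, matrix, _ = small_analysis
        perm = np.random.default_rng(5).permutation(len(cohort))
        cohort_p = cohort.iloc[perm].reset_index(drop=True)
        matrix_p = BiomarkerMatrix(
            matrix.values.iloc[perm], matrix.below_lod.iloc[perm], LOG_SCALED
        )
        a = run_mwas(matrix, cohort, m_eff=2, biomarkers=["tyrosine", "glucose"])
        b = run_mwas(matrix_p, cohort_p, m_eff=2, biomarkers=["tyrosine", "glucose"])
        np.testing.assert_allclose(a["beta"], b["beta"], atol=1e-8)

    def test_null_family_wise_error(self):
        """No true effects: the Bonferroni-corrected hit rate stays near
        the nominal family-wise level (desk-scale simulation)."""
        families_with_hit = 0
        n_seeds = 40
        for seed in range(400, 400 + n_seeds):
            study = generate_study(
                small_config(true_effects={}, bmi_mediation=0.0, seed=seed)
            )
            cohort = classify_cohort(study.cohort)
            cohort, matrix, _ = preprocess_matrix(cohort, study.biomarkers)
            res = run_mwas(matrix, cohort)
            families_with_hit += int(res["significant"].any())
        # 3-sigma binomial envelope around 0.05
        assert families_with_hit / n_seeds <= 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / n_seeds
        )


class TestSensitivitySuite:
    def test_full_mediation_zeroes_adjusted_effect(self):
        """bmi_mediation = 1: +BMI beta ~ 0 while main beta ~ truth."""
        mains, adjs = [], []
        truth = 0.2  # full mediation of a 0.2 SD effect through BMI
        for seed in range(300, 320):
            study = generate_study(
                small_config(
                    true_effects={"tyrosine": truth},
                    bmi_mediation=1.0,
                    bmi_axis_sd=0.0,
                    seed=seed,
                )
            )
            cohort = classify_cohort(study.cohort)
            cohort, matrix, _ = preprocess_matrix(cohort, study.biomarkers)
            res = sensitivity_suite(matrix, cohort, ["tyrosine"], m_eff=2)
            mains.append(res.query("model == 'main'")["beta"].iloc[0])
            adjs.append(res.query("model == 'bmi'")["beta"].iloc[0])
        assert np.mean(mains) == pytest.approx(truth, abs=0.05)
        assert np.mean(adjs) == pytest.approx(0.0, abs=0.05)

    def test_model_tags_and_timing_coefficients(self, small_analysis):
        cohort, matrix, study = small_analysis
        res = sensitivity_suite(
            matrix, cohort, ["tyrosine"], pgs=study.pgs, m_eff=2
        )
        tags = set(res["model"])
        assert {
            "main", "bmi", "waist", "t2d", "pgs",
            "sex_M", "sex_F", "sex_interaction", "timing",
        } <= tags
        timing = res.query("model == 'timing'")
        assert len(timing) == 5  # one coefficient per gestational window
        # homogeneous truth: window estimates mutually consistent
        betas, ses = timing["beta"].to_numpy(), timing["se"].to_numpy()
        for i in range(5):
            for j in range(i + 1, 5):
                assert abs(betas[i] - betas[j]) < 2.5 * (ses[i] + ses[j])

    def test_pgs_missing_target_warns_and_skips(self, small_analysis):
        cohort, matrix, study = small_analysis
        with pytest.warns(UserWarning, match="polygenic"):
            res = sensitivity_suite(
                matrix, cohort, ["bm_020"], pgs=study.pgs, m_eff=2
            )
        assert "pgs" not in set(res["model"])

    def test_null_interaction_p_uniform(self):
        """No sex effect in truth: interaction p-values look U(0,1)."""
        pvals = []
        for seed in range(500, 540):
            study = generate_study(
                small_config(true_effects={"tyrosine": 0.2}, seed=seed)
            )
            cohort = classify_cohort(study.cohort)
            cohort, matrix, _ = preprocess_matrix(cohort, study.biomarkers)
            res = sensitivity_suite(matrix, cohort, ["tyrosine"], m_eff=2)
            pvals.append(
                res.query("model == 'sex_interaction'")["p"].iloc[0]
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestDescribeCohort:
    def _cohort(self, n0, n1, k0, k1):
        rows = []
        for i in range(n0):
            rows.append({"g": 0, "cat": int(i < k0), "age": 50 + i % 7})
        for i in range(n1):
            rows.append({"g": 1, "cat": int(i < k1), "age": 51 + i % 7})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "n0, n1, k0, k1, expected_p",
        [
            (464, 480, 200, 225, 0.24),  # sex, males
            (464, 480, 55, 61, 0.69),    # cholesterol-lowering medication
            (464, 480, 38, 61, 0.02),    # type 2 diabetes
        ],
    )
    def test_chi_square_reproduces_printed_p(self, n0, n1, k0, k1, expected_p):
        cohort = self._cohort(n0, n1, k0, k1)
        out = describe_cohort(
            cohort, "g", continuous=("age",), categorical=("cat",)
        )
        p = out.loc[out["variable"] == "cat", "p"].iloc[0]
        assert round(p, 2) == expected_p

    def test_identical_groups(self):
        cohort = self._cohort(50, 50, 10, 10)
        out = describe_cohort(
            cohort, "g", continuous=(), categorical=("cat",)
        )
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_continuous_t_statistic_zero_for_identical(self):
        df = pd.DataFrame(
            {"g": [0] * 10 + [1] * 10, "age": list(range(10)) * 2}
        )
        out = describe_cohort(df, "g", continuous=("age",), categorical=())
        assert out["statistic"].iloc[0] == pytest.approx(0.0)

    def test_small_group_raises(self):
        df = pd.DataFrame({"g": [0, 1, 1], "age": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="n >= 2"):
            describe_cohort(df, "g", continuous=("age",), categorical=())
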