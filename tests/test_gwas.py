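"""Logistic GWAS engine: IRLS correctness, Wald inference, scan invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spirogwas import ScanSpec, fit_logistic, genomic_lambda, interaction_scan, run_scan, wald_test
from spirogwas.gwas import SingularDesignError, default_covariates
from .conftest import make_cohort


def table_2x2(a, b, c, d):
    """y, x for a 2×2 table: a = cases with x=1, b = controls with x=1,
    c = cases with x=0, d = controls with x=0."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return y, x


class TestFitLogistic:
    def test_balanced_table_gives_zero_beta(self):
        y, x = table_2x2(10, 10, 10, 10)
        fit = fit_logistic(np.column_stack([np.ones_like(y), x]), y)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("a,b,c,d", [(12, 5, 7, 9), (3, 14, 8, 2), (20, 20, 5, 30)])
    def test_matches_contingency_closed_form(self, a, b, c, d):
        y, x = table_2x2(a, b, c, d)
        fit = fit_logistic(np.column_stack([np.ones_like(y), x]), y)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)
        assert fit.se[1] == pytest.approx(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-8)

    def test_optimum_beats_surrounding_grid(self):
        rng = np.random.default_rng(12)
        X = np.column_stack([np.ones(30), rng.normal(size=30), rng.normal(size=30)])
        y = (rng.random(30) < 0.4).astype(float)
        fit = fit_logistic(X, y)

        def loglik(beta):
            eta = X @ beta
            return float(y @ eta - np.logaddexp(0, eta).sum())

        best = loglik(fit.beta)
        for d0 in (-0.3, 0.0, 0.3):
            for d1 in (-0.3, 0.0, 0.3):
                for d2 in (-0.3, 0.0, 0.3):
                    assert loglik(fit.beta + np.array([d0, d1, d2])) <= best + 1e-9

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        n = 400
        X = np.column_stack([np.ones(n), rng.integers(0, 3, n).astype(float),
                             rng.normal(50, 10, n), rng.normal(size=n)])
        eta = -1.0 + 0.4 * X[:, 1] + 0.02 * (X[:, 2] - 50)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic(X, y)
        theirs = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.beta, theirs.params, atol=1e-6)
        np.testing.assert_allclose(ours.se, theirs.bse, rtol=1e-5)

    def test_perfect_separation_flagged_not_silent(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = np.array([0.0] * 10 + [1.0] * 10)
        fit = fit_logistic(np.column_stack([np.ones_like(y), x]), y)
        assert not fit.converged
        assert fit.message

    def test_singular_design_names_columns(self):
        n = 50
        rng = np.random.default_rng(14)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = (rng.random(n) < 0.5).astype(float)
        with pytest.raises(SingularDesignError, match="dup"):
            fit_logistic(X, y, column_names=["intercept", "x", "dup"])


class TestWald:
    def test_null_and_reference_quantile(self):
        assert wald_test(0.0, 1.0) == pytest.approx(1.0)
        assert wald_test(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)

    def test_matches_normal_survival_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            beta, se = rng.normal(), rng.uniform(0.1, 2.0)
            oracle = 2.0 * stats.norm.sf(abs(beta / se))
            assert wald_test(beta, se) == pytest.approx(oracle, abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestGenomicLambda:
    def test_exact_at_median_p(self):
        assert genomic_lambda([0.5] * 11) == pytest.approx(1.0)

    def test_uniform_null_is_calibrated(self):
        rng = np.random.default_rng(16)
        lam = genomic_lambda(rng.uniform(size=100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_inflation_monotone(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=5000)
        assert genomic_lambda(p / 2) > genomic_lambda(p)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda([])


class TestCovariateConventions:
    def test_default_sets(self):
        assert default_covariates("fixed70", "never") == ("sex", "age", "height")
        assert default_covariates("lln", "never") == ()
        assert default_covariates("fixed70", "ever") == (
            "sex", "age", "height", "pack_years", "current_smoker")
        assert default_covariates("lln", "ever") == ("pack_years", "current_smoker")


class TestRunScan:
    def test_null_scan_calibration(self, small_cohort, small_labels):
        summary = run_scan(small_cohort, small_labels, ScanSpec("lln", "never"))
        res = summary.results
        assert res["converged"].mean() > 0.95
        frac = (res["p"] < 0.05).mean()
        assert 0.01 <= frac <= 0.10  # 300 SNPs: wide binomial band around 5 %
        assert summary.n_cases + summary.n_controls == 2000

    def test_effect_allele_is_minor(self, small_cohort, small_labels):
        res = run_scan(small_cohort, small_labels, ScanSpec("lln", "never")).results
        assert (res["eaf"].dropna() <= 0.5 + 1e-12).all()
        assert np.allclose(res["or_"].dropna(),
                           np.exp(res["beta"].dropna()), rtol=1e-12)

    def test_invariant_to_subject_and_snp_order(self, small_cohort, small_labels, reference):
        base = run_scan(small_cohort, small_labels, ScanSpec("fixed70", "never")).results
        rng = np.random.default_rng(18)
        perm_s = rng.permutation(small_cohort.n_subjects)
        perm_j = rng.permutation(small_cohort.n_snps)
        from spirogwas.cohort import Cohort

        shuffled = Cohort(
            subjects=small_cohort.subjects.iloc[perm_s].reset_index(drop=True),
            genotypes=small_cohort.genotypes[perm_s][:, perm_j],
            snp_info=small_cohort.snp_info.iloc[perm_j].reset_index(drop=True),
        )
        labels_perm = small_labels.iloc[perm_s].reset_index(drop=True)
        perm = run_scan(shuffled, labels_perm, ScanSpec("fixed70", "never")).results
        merged = base.set_index("snp_id").join(perm.set_index("snp_id"),
                                               rsuffix="_perm").dropna()
        np.testing.assert_allclose(merged["beta"], merged["beta_perm"], atol=1e-8)
        np.testing.assert_allclose(merged["p"], merged["p_perm"], atol=1e-8)

    def test_covariate_scaling_leaves_genotype_inference_unchanged(
            self, small_cohort, small_labels):
        spec = ScanSpec("fixed70", "never")
        base = run_scan(small_cohort, small_labels, spec).results
        scaled_cohort = small_cohort
        scaled_cohort = type(small_cohort)(
            subjects=small_cohort.subjects.assign(
                height=small_cohort.subjects["height"] * 100.0),
            genotypes=small_cohort.genotypes,
            snp_info=small_cohort.snp_info,
        )
        scaled = run_scan(scaled_cohort, small_labels, spec).results
        ok = base["converged"] & scaled["converged"]
        np.testing.assert_allclose(base.loc[ok, "beta"], scaled.loc[ok, "beta"], atol=1e-8)
        np.testing.assert_allclose(base.loc[ok, "se"], scaled.loc[ok, "se"], atol=1e-8)

    def test_zero_cases_rejected(self, small_cohort, small_labels):
        none = small_labels.assign(lln=False)
        with pytest.raises(ValueError):
            run_scan(small_cohort, none, ScanSpec("lln", "never"))

    def test_empty_stratum_rejected(self, small_cohort, small_labels):
        with pytest.raises(ValueError):
            run_scan(small_cohort, small_labels, ScanSpec("lln", "ever"))


class TestInteractionScan:
    def test_null_interaction_not_significant_en_masse(self, mixed_cohort, mixed_labels):
        res = interaction_scan(mixed_cohort, mixed_labels, "lln", range(40))
        ok = res.dropna(subset=["p_interaction"])
        assert (ok["p_interaction"] < 0.05).mean() < 0.25

    def test_no_ever_smokers_is_degenerate(self, small_cohort, small_labels):
        with pytest.raises(SingularDesignError):
            interaction_scan(small_cohort, small_labels, "lln", [0])


class TestQQCalibration:
    def test_null_p_uniformity_across_seeds(self, reference):
        """KS test of p-uniformity on null scans over 10 seeds; allow the
        expected false-positive rate at alpha = 0.01."""
        from spirogwas import SimConfig, simulate_cohort, classify_obstruction

        rejections = 0
        for seed in range(10):
            cfg = SimConfig(n_subjects=600, n_snps=120, stratum_mix=1.0,
                            maf_range=(0.2, 0.5), missing_genotype_rate=0.0,
                            seed=500 + seed)
            cohort = simulate_cohort(cfg, reference)
            labels = classify_obstruction(cohort, reference)
            res = run_scan(cohort, labels, ScanSpec("lln", "never")).results
            p = res.loc[res["converged"], "p"].to_numpy()
            if stats.kstest(p, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= 2
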