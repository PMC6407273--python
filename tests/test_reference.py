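"""LMS evaluation, obstruction classification, and concordance arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from spirogwas.reference import (
    CrossClassification,
    DomainError,
    LmsReference,
    classify_obstruction,
    concordance_stats,
    cross_classification,
    default_reference,
    lms_lln,
    percent_predicted,
)
from .conftest import make_cohort


def flat_reference(M=80.0, S=0.1, L=1.0):
    tab = pd.DataFrame({"age": [18.0, 95.0], "M": [M, M], "S": [S, S], "L": [L, L]})
    return LmsReference(tables={"male": tab.copy(), "female": tab.copy()})


class TestLmsLln:
    def test_linear_case_closed_form(self):
        # L=1: LLN = M (1 + S z_0.05) = 80 (1 − 0.16449)
        assert lms_lln(flat_reference(), "male", 50, 175) == pytest.approx(66.8412, abs=1e-3)

    def test_degenerate_dispersion_returns_median(self):
        assert lms_lln(flat_reference(S=1e-12), "male", 50, 175) == pytest.approx(80.0)

    @pytest.mark.parametrize("L", [-0.5, 0.0, 0.5, 1.0, 1.5])
    @pytest.mark.parametrize("M,S", [(80.0, 0.05), (75.0, 0.1), (90.0, 0.15)])
    def test_matches_numerical_cdf_inversion(self, L, M, S):
        """Root-finding oracle: invert the LMS CDF at probability 0.05."""
        ref = flat_reference(M=M, S=S, L=L)

        def cdf(x):
            if abs(L) < 1e-12:
                z = np.log(x / M) / S
            else:
                z = ((x / M) ** L - 1.0) / (L * S)
            return stats.norm.cdf(z)

        oracle = optimize.brentq(lambda x: cdf(x) - 0.05, M * 0.2, M * 2.0, xtol=1e-10)
        assert lms_lln(ref, "female", 40, 160) == pytest.approx(oracle, rel=1e-9)

    def test_monotone_in_M_and_S(self):
        """LLN increases with M and (for L>0) decreases with S."""
        for L in (0.5, 1.0, 1.5):
            vals_m = [lms_lln(flat_reference(M=m, S=0.1, L=L), "male", 50, 175)
                      for m in (70, 80, 90)]
            assert vals_m == sorted(vals_m)
            vals_s = [lms_lln(flat_reference(M=80, S=s, L=L), "male", 50, 175)
                      for s in (0.05, 0.1, 0.15)]
            assert vals_s == sorted(vals_s, reverse=True)

    def test_outside_domain_raises(self, reference):
        with pytest.raises(DomainError):
            lms_lln(reference, "male", 110, 175)
        with pytest.raises(DomainError):
            lms_lln(reference, "plant", 50, 175)


class TestPercentPredicted:
    def test_observed_equal_to_median_is_100(self):
        assert percent_predicted(flat_reference(), "male", 50, 175, 80.0) == pytest.approx(100.0)
        assert percent_predicted(flat_reference(), "male", 50, 175, 40.0) == pytest.approx(50.0)

    def test_spot_check_against_table_M(self, reference):
        L, M, S = reference.coefficients("female", 30.0, 165.0)
        assert percent_predicted(reference, "female", 30.0, 165.0, 0.9 * M) == pytest.approx(90.0)


class TestClassification:
    def test_boundary_and_stratum_rules(self):
        # subject ratios: 69.9 (fixed70 only), 66 (both if LLN≈68), 75 (neither)
        ref = flat_reference(M=80.0, S=0.0895, L=1.0)  # LLN ≈ 68.2
        fvc = np.array([4.0, 4.0, 4.0])
        fev1 = fvc * np.array([0.699, 0.66, 0.75])
        cohort = make_cohort(np.zeros((3, 1)), fev1=fev1, fvc=fvc,
                             pack_years=np.array([0.0, 10.0, 3.0]))
        lab = classify_obstruction(cohort, ref)
        assert lab["fixed70"].tolist() == [True, True, False]
        assert lab["lln"].tolist() == [False, True, False]
        # never / ever / excluded (pack-years 3 is in the excluded gap)
        assert lab["stratum"].tolist() == ["never", "ever", "excluded"]

    def test_missing_spirometry_flagged_invalid(self):
        cohort = make_cohort(np.zeros((2, 1)), fev1=np.array([3.0, np.nan]),
                             fvc=np.array([4.0, 4.0]))
        lab = classify_obstruction(cohort, flat_reference())
        assert lab["valid"].tolist() == [True, False]
        with pytest.raises(ValueError):
            cross_classification(lab[lab["valid"]].iloc[0:0], "never")


class TestCrossClassification:
    def test_study_never_smoker_counts(self):
        cc = CrossClassification(n=5070, n70=548, nlln=401, nboth=371)
        assert cc.n_union == 578
        assert cc.n_discordant == 207

    def test_perfect_agreement_and_disjoint(self):
        assert CrossClassification(10, 3, 3, 3).n_discordant == 0
        assert CrossClassification(10, 1, 1, 0).n_discordant == 2

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            CrossClassification(10, 3, 2, 3)
        with pytest.raises(ValueError):
            CrossClassification(5, 4, 4, 1)


class TestConcordanceStats:
    def test_never_smoker_percentages(self):
        st = concordance_stats(CrossClassification(5070, 548, 401, 371))
        assert st.pct_concordant == pytest.approx(95.92, abs=0.01)
        assert st.pct_discordant == pytest.approx(4.08, abs=0.01)
        assert st.pct_discordant_among_union == pytest.approx(35.81, abs=0.01)
        assert st.pct_overlap_cases == pytest.approx(64.19, abs=0.01)
        assert st.rounded() == {
            "pct_concordant": 96, "pct_discordant": 4,
            "pct_discordant_among_union": 36, "pct_overlap_cases": 64,
        }

    def test_ever_smoker_percentages(self):
        st = concordance_stats(CrossClassification(4855, 1107, 833, 802))
        assert st.rounded()["pct_concordant"] == 93
        assert st.rounded()["pct_discordant_among_union"] == 30

    def test_perfect_agreement(self):
        st = concordance_stats(CrossClassification(100, 10, 10, 10))
        assert (st.pct_concordant, st.pct_discordant) == (100.0, 0.0)
        assert (st.pct_discordant_among_union, st.pct_overlap_cases) == (0.0, 100.0)

    def test_no_cases_flags_union_fields(self):
        st = concordance_stats(CrossClassification(100, 0, 0, 0))
        assert st.pct_discordant_among_union is None
        assert st.pct_overlap_cases is None

    @pytest.mark.parametrize("scale", [2, 7, 100])
    def test_invariant_under_uniform_count_scaling(self, scale):
        a = concordance_stats(CrossClassification(500, 60, 40, 30))
        b = concordance_stats(
            CrossClassification(500 * scale, 60 * scale, 40 * scale, 30 * scale))
        assert a == b


def test_lln_prevalence_five_percent_under_matching_reference(reference):
    """Never-smokers drawn with standard-normal latent z from the classifying
    reference have LLN-case prevalence 5 % up to sampling error (ever-smokers
    carry the pack-years liability shift and sit above it by design)."""
    from spirogwas import SimConfig, simulate_cohort

    cfg = SimConfig(n_subjects=20000, n_snps=2, spirometry_noise=1.0,
                    stratum_mix=1.0, missing_genotype_rate=0.0, seed=9)
    lab = classify_obstruction(simulate_cohort(cfg, reference), reference)
    prev = lab["lln"].mean()
    assert prev == pytest.approx(0.05, abs=0.005)
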