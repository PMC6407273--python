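"""Fixed-effects meta-analysis, direction strings, replication rule, cis-eQTL."""

import numpy as np
import pandas as pd
import pytest

from spirogwas import CohortEstimate, cis_eqtl_scan, direction_string, fixed_effects_meta, replication_call, simulate_expression


def est(beta, se, cohort="c", snp="rs1"):
    return CohortEstimate(cohort, snp, beta, se)


class TestFixedEffectsMeta:
    def test_single_study_passthrough(self):
        mr = fixed_effects_meta([est(0.3, 0.1)])
        assert mr.beta_meta == pytest.approx(0.3)
        assert mr.se_meta == pytest.approx(0.1)
        assert mr.i2 == 0.0

    def test_two_identical_studies(self):
        mr = fixed_effects_meta([est(0.3, 0.1, "a"), est(0.3, 0.1, "b")])
        assert mr.beta_meta == pytest.approx(0.3)
        assert mr.se_meta == pytest.approx(0.1 / np.sqrt(2))
        assert mr.i2 == 0.0

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            k = rng.integers(2, 8)
            betas = rng.normal(0, 0.5, k)
            ses = rng.uniform(0.05, 0.5, k)
            mr = fixed_effects_meta(
                [est(b, s, f"c{i}") for i, (b, s) in enumerate(zip(betas, ses))])
            # WLS oracle: intercept-only weighted regression
            w = 1.0 / ses**2
            X = np.ones((k, 1))
            Xw = X * w[:, None]
            beta_wls = np.linalg.solve(Xw.T @ X, Xw.T @ betas)[0]
            se_wls = np.sqrt(np.linalg.inv(Xw.T @ X)[0, 0])
            assert mr.beta_meta == pytest.approx(beta_wls, abs=1e-10)
            assert mr.se_meta == pytest.approx(se_wls, abs=1e-10)

    def test_invariant_to_study_order_and_global_flip(self):
        studies = [est(0.2, 0.1, "a"), est(0.4, 0.2, "b"), est(-0.1, 0.15, "c")]
        mr1 = fixed_effects_meta(studies)
        mr2 = fixed_effects_meta(studies[::-1])
        assert mr1.beta_meta == pytest.approx(mr2.beta_meta)
        assert mr1.q_stat == pytest.approx(mr2.q_stat)
        flipped = fixed_effects_meta(
            [CohortEstimate(e.cohort_id, e.snp_id, -e.beta, e.se) for e in studies])
        assert flipped.beta_meta == pytest.approx(-mr1.beta_meta)
        assert flipped.p_meta == pytest.approx(mr1.p_meta)

    def test_i2_zero_when_betas_equal_and_bounded(self):
        assert fixed_effects_meta([est(0.2, 0.1, "a"), est(0.2, 0.3, "b")]).i2 == 0.0
        rng = np.random.default_rng(42)
        for _ in range(20):
            studies = [est(rng.normal(), rng.uniform(0.05, 0.3), f"c{i}")
                       for i in range(4)]
            assert 0.0 <= fixed_effects_meta(studies).i2 <= 100.0

    def test_mixed_snps_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_meta([est(0.1, 0.1, snp="rs1"), est(0.1, 0.1, snp="rs2")])
        with pytest.raises(ValueError):
            fixed_effects_meta([])


class TestDirectionString:
    def test_band_and_signs(self):
        assert direction_string([1.00]) == "0"
        assert direction_string([0.90]) == "−"
        assert direction_string([1.36, 1.21, 1.20, 1.30, 1.25]) == "+++++"
        # closed band at the boundaries
        assert direction_string([0.95, 1.05, 0.949, 1.051]) == "00−+"

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            direction_string([0.0])


class TestReplicationCall:
    def test_published_borderline_example(self):
        """p = 0.034 with 2 candidates misses the 0.05/2 = 0.025 bar."""
        mr = fixed_effects_meta([est(0.19, 0.0896, "a"), est(0.19, 0.0896, "b")])
        assert mr.p_meta == pytest.approx(0.0027, abs=0.001)
        call = replication_call(mr, n_candidates=2, directions="++")
        assert call["threshold"] == 0.025
        weak = replication_call(
            type(mr)(mr.snp_id, mr.beta_meta, mr.se_meta, 0.034, mr.q_stat,
                     mr.i2, "++", mr.cohorts), n_candidates=2)
        assert not weak["replicated"]

    def test_opposing_directions_block_replication(self):
        mr = fixed_effects_meta([est(0.5, 0.05, "a"), est(0.5, 0.05, "b")])
        assert mr.p_meta < 0.025
        assert not replication_call(mr, 2, directions="++−")["replicated"]
        assert replication_call(mr, 2, directions="++0")["replicated"]

    def test_single_candidate_reduces_to_alpha(self):
        mr = fixed_effects_meta([est(0.5, 0.2, "a")])
        call = replication_call(mr, 1)
        assert call["threshold"] == 0.05
        assert call["replicated"] == (mr.p_meta < 0.05)


class TestCisEqtl:
    @pytest.fixture()
    def planted(self, small_cohort):
        expr, annot = simulate_expression(
            small_cohort, [(0, "hit_probe", 1.0)], noise_sd=0.5, seed=3,
            n_null_probes=0)
        # one probe inside the window, one just outside
        far = annot.iloc[[0]].assign(probe_id="far_probe",
                                     position=annot["position"].iloc[0] + 2_500_000)
        annot = pd.concat([annot, far], ignore_index=True)
        expr = pd.concat([expr, expr.rename(index={"hit_probe": "far_probe"})])
        return expr, annot

    def test_slope_recovery_and_window_rule(self, small_cohort, planted):
        expr, annot = planted
        snp = small_cohort.snp_info.iloc[0]
        res = cis_eqtl_scan("m0", int(snp["chromosome"]), int(snp["position"]),
                            small_cohort.genotypes[:, 0], expr, annot)
        assert set(res["probe_id"]) == {"hit_probe"}  # 2.5 Mb probe excluded
        row = res.iloc[0]
        assert abs(row["slope"] - 1.0) <= 2 * row["se"]
        assert row["significant"]

    def test_empty_window_is_empty_result_not_error(self, small_cohort, planted):
        expr, annot = planted
        res = cis_eqtl_scan("m5", 22, 1, small_cohort.genotypes[:, 5], expr, annot)
        assert res.empty

    def test_null_probes_bonferroni_controlled(self, small_cohort):
        """With no planted effect, significant calls at 0.05/n_probes are rare."""
        expr, annot = simulate_expression(small_cohort, [], noise_sd=1.0,
                                          seed=4, n_null_probes=40)
        annot = annot.assign(chromosome=small_cohort.snp_info["chromosome"].iloc[0],
                             position=small_cohort.snp_info["position"].iloc[0] + 1000)
        snp = small_cohort.snp_info.iloc[0]
        res = cis_eqtl_scan("m0", int(snp["chromosome"]), int(snp["position"]),
                            small_cohort.genotypes[:, 0], expr, annot)
        assert len(res) == 40
        assert res["significant"].sum() <= 1
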