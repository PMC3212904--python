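"""Odds ratios, Wald intervals, IRLS logistic regression, and power."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import grskit as gk
from grskit.association import design_log_additive, logistic_fit


class TestAllelicTest:
    def test_identical_rows_null(self):
        res = gk.allelic_test(gk.TwoByTwo(10, 90, 10, 90))
        assert res.or_point == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_interval(self):
        res = gk.allelic_test(gk.TwoByTwo(20, 80, 10, 90))
        assert res.or_point == pytest.approx(2.25)
        se = math.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
        assert res.ci_low == pytest.approx(2.25 * math.exp(-1.96 * se), rel=1e-3)
        assert res.ci_high == pytest.approx(2.25 * math.exp(1.96 * se), rel=1e-3)
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.99, 5.09)

    def test_reference_interval_reproduced(self):
        """The published extreme-cutoff row pins down the SE/CI convention."""
        res = gk.allelic_test(gk.TwoByTwo(27, 342, 3, 500))
        assert round(res.or_point, 2) == 13.16
        assert round(res.ci_low, 2) == 3.96
        assert round(res.ci_high, 2) == 43.72

    def test_zero_cell_haldane_flagged(self):
        res = gk.allelic_test(gk.TwoByTwo(5, 95, 0, 100))
        assert res.haldane and np.isfinite(res.ci_high)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            gk.allelic_test(gk.TwoByTwo(0, 0, 10, 90))

    @given(st.integers(0, 5000))
    def test_ci_and_p_consistent(self, seed):
        """p < 0.05 iff the 95% CI excludes 1."""
        rng = np.random.default_rng(seed)
        t = gk.TwoByTwo(*(int(x) for x in rng.integers(0, 200, 4)))
        if t.a + t.b == 0 or t.c + t.d == 0:
            return
        res = gk.allelic_test(t)
        excludes_one = res.ci_low > 1.0 or res.ci_high < 1.0
        assert (res.p_value < 0.05) == excludes_one


class TestCarriageCompound:
    def test_single_snp_carriage_equals_dominant_table(self, seven_snp_cohort):
        gm, ph = seven_snp_cohort
        snp = "rs2066845"
        res = gk.carriage_test(gm, ph, [snp])
        dos, _ = gm.column(snp)
        is_case = np.array(
            [dict(zip(ph.sample_ids, ph.is_case))[s] for s in gm.sample_ids])
        carrier = dos >= 1
        t = gk.TwoByTwo(int((carrier & is_case).sum()),
                        int((~carrier & is_case).sum()),
                        int((carrier & ~is_case).sum()),
                        int((~carrier & ~is_case).sum()))
        assert res.or_point == pytest.approx(gk.wald_or(t).or_point)

    def test_compound_exposure_definitions(self):
        variants = [gk.VariantSpec(snp_id=s) for s in ("a", "b")]
        dosage = np.array([[1, 1], [2, 0], [1, 0], [0, 0]], dtype=np.int8)
        gm = gk.GenotypeMatrix(["w", "x", "y", "z"], variants, dosage,
                               np.zeros((4, 2), dtype=bool))
        ph = gk.PhenotypeVector(["w", "x", "y", "z"],
                                np.array([1, 1, 0, 0], dtype=bool))
        res = gk.compound_test(gm, ph, ["a", "b"])
        # double het and homozygote exposed; single het and wild type not
        assert res.table.a == 2 and res.table.c == 0
        assert res.haldane  # no exposed controls -> corrected, finite CI
        assert np.isfinite(res.ci_high)

    def test_carriage_against_stratum_frequency_oracle(self):
        """Carrier OR on simulated data vs the analytic stratum law."""
        raf, or_, prev = 0.1, 2.5, 0.01
        spec = gk.VariantSpec(snp_id="s", control_raf=raf)
        cfg = gk.CohortSimConfig(variants=[spec], per_allele_or={"s": or_},
                                 n_case=4000, n_control=4000,
                                 prevalence=prev, seed=8)
        gm, ph = gk.simulate_cohort(cfg)
        res = gk.carriage_test(gm, ph, ["s"])
        b0 = gk.calibrate_intercept(cfg)
        g1 = gk.expected_genotype_freq_in_stratum(raf, or_, b0, "case")
        g0 = gk.expected_genotype_freq_in_stratum(raf, or_, b0, "control")
        carrier_or = ((g1[1] + g1[2]) / g1[0]) / ((g0[1] + g0[2]) / g0[0])
        assert res.or_point == pytest.approx(carrier_or, rel=0.15)


class TestLogisticFit:
    def test_single_binary_covariate_closed_form(self):
        """Saturated 2x2 logistic equals the cross-product OR exactly."""
        x = np.repeat([0, 0, 1, 1], [80, 20, 60, 40])
        y = np.repeat([0, 1, 0, 1], [80, 20, 60, 40])
        X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
        fit = logistic_fit(X, y.astype(float))
        assert fit.converged
        closed = (40 * 80) / (60 * 20)
        assert math.exp(fit.coefficients[1]) == pytest.approx(closed, abs=1e-8)

    def test_matches_statsmodels(self, seven_snp_cohort):
        import statsmodels.api as sm
        gm, ph = seven_snp_cohort
        panel = gm.snp_ids[:4]
        X, names, keep = design_log_additive(gm, panel)
        status = dict(zip(ph.sample_ids, ph.is_case))
        y = np.array([status[s] for s in gm.sample_ids])[keep].astype(float)
        ours = logistic_fit(X, y, term_names=names)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(ours.coefficients, ref.params, atol=1e-6)
        assert np.allclose(ours.standard_errors, ref.bse, rtol=1e-4)

    def test_loglik_nondecreasing(self, seven_snp_cohort):
        gm, ph = seven_snp_cohort
        X, names, keep = design_log_additive(gm, gm.snp_ids)
        status = dict(zip(ph.sample_ids, ph.is_case))
        y = np.array([status[s] for s in gm.sample_ids])[keep].astype(float)
        fit = logistic_fit(X, y)
        assert all(b >= a - 1e-9 for a, b in
                   zip(fit.loglik_trace, fit.loglik_trace[1:]))

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.zeros(20)])
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(ValueError, match="rank deficient"):
            logistic_fit(X, y, term_names=["intercept", "allzero"])

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)]
        X = np.column_stack([np.ones(40), x])
        fit = logistic_fit(X, y)
        assert fit.separated and not fit.converged

    def test_dominant_fit_reproduces_carriage_or(self, seven_snp_cohort):
        gm, ph = seven_snp_cohort
        snp = "rs7517847"
        res = gk.carriage_test(gm, ph, [snp])
        dos, _ = gm.column(snp)
        status = dict(zip(ph.sample_ids, ph.is_case))
        y = np.array([status[s] for s in gm.sample_ids]).astype(float)
        X = np.column_stack([np.ones(len(y)), (dos >= 1).astype(float)])
        fit = logistic_fit(X, y)
        assert math.exp(fit.coefficients[1]) == pytest.approx(res.or_point,
                                                              abs=1e-8)

    def test_multivariate_fit_table(self, seven_snp_cohort):
        gm, ph = seven_snp_cohort
        fit, table = gk.multivariate_fit(gm, ph, gm.snp_ids)
        assert set(table["term"]) == set(gm.snp_ids)
        assert (table["ci_low"] <= table["or"]).all()
        assert (table["or"] <= table["ci_high"]).all()

    def test_genotype_coding_columns(self, seven_snp_cohort):
        gm, ph = seven_snp_cohort
        fit, table = gk.multivariate_fit(gm, ph, ["rs7517847", "rs1373692"],
                                         coding="genotype")
        assert len(table) == 4  # 1-copy and 2-copy terms per SNP


class TestPower:
    def test_null_or_gives_alpha(self):
        assert gk.power_allelic(369, 503, 0.59, 1.0) == pytest.approx(
            0.05, abs=1e-6)

    def test_reference_power_value(self):
        p = gk.power_allelic(369, 503, 0.59, 1.32)
        assert 0.78 <= p <= 0.82

    def test_analytic_matches_monte_carlo(self):
        rng = np.random.default_rng(2024)
        for _ in range(3):
            raf = rng.uniform(0.15, 0.7)
            or_ = rng.uniform(1.2, 1.8)
            analytic = gk.power_allelic(300, 400, raf, or_)
            mc, se = gk.power_allelic_mc(300, 400, raf, or_,
                                         n_replicates=800,
                                         seed=int(rng.integers(1 << 30)))
            assert abs(analytic - mc) <= 2.5 * max(se, 0.005)
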