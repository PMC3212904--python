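"""Generative model: intercept calibration, LD blocks, rejection sampling."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import expit

import grskit as gk
from grskit.synthetic_cohort import _score_pmf


def _single_snp_config(raf=0.5, or_=2.0, prevalence=0.1, seed=0, **kw):
    spec = gk.VariantSpec(snp_id="s", control_raf=raf)
    return gk.CohortSimConfig(variants=[spec], per_allele_or={"s": or_},
                              n_case=kw.pop("n_case", 50),
                              n_control=kw.pop("n_control", 50),
                              prevalence=prevalence, seed=seed, **kw)


class TestCalibrateIntercept:
    def test_null_effects_give_logit_prevalence(self):
        cfg = _single_snp_config(or_=1.0, prevalence=0.2)
        assert gk.calibrate_intercept(cfg) == pytest.approx(
            math.log(0.2 / 0.8), abs=1e-8)

    def test_symmetric_prevalence_gives_zero(self):
        cfg = _single_snp_config(or_=1.0, prevalence=0.5)
        assert gk.calibrate_intercept(cfg) == pytest.approx(0.0, abs=1e-8)

    def test_matches_three_genotype_enumeration(self):
        """Independent brute-force solution of the 3-genotype equation."""
        cfg = _single_snp_config(raf=0.5, or_=2.0, prevalence=0.1)

        def gap(b0):
            p, q = 0.5, 0.5
            geno = [q * q, 2 * p * q, p * p]
            return sum(g * expit(b0 + math.log(2.0) * c)
                       for c, g in enumerate(geno)) - 0.1
        expected = brentq(gap, -20, 5, xtol=1e-12)
        assert gk.calibrate_intercept(cfg) == pytest.approx(expected, abs=1e-8)

    def test_prevalence_equation_holds_for_many_snps(self):
        specs = gk.full_panel()
        cfg = gk.CohortSimConfig(variants=specs,
                                 per_allele_or=gk.univariate_ors(),
                                 n_case=10, n_control=10, prevalence=0.005,
                                 ld_pairs=list(gk.LD_PAIRS))
        b0 = gk.calibrate_intercept(cfg)
        scores, probs = _score_pmf(cfg)
        assert float(probs @ expit(b0 + scores)) == pytest.approx(0.005,
                                                                  abs=1e-6)


class TestHaplotypePair:
    def test_equilibrium_factorizes(self):
        hp = gk.make_haplotype_pair(0.3, 0.6, 0.0)
        assert hp.freq_AB == pytest.approx(0.18)

    def test_full_coupling_two_haplotypes(self):
        hp = gk.make_haplotype_pair(0.5, 0.5, 1.0)
        assert hp.freq_Ab == pytest.approx(0.0, abs=1e-12)
        assert hp.freq_aB == pytest.approx(0.0, abs=1e-12)
        assert hp.freq_AB == pytest.approx(0.5)

    def test_marginals_preserved(self):
        hp = gk.make_haplotype_pair(0.22, 0.04, 0.99)
        assert hp.p_a == pytest.approx(0.22, abs=1e-9)
        assert hp.p_b == pytest.approx(0.04, abs=1e-9)

    def test_frequencies_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            gk.make_haplotype_pair(0.0, 0.5, 0.5)

    def test_dprime_round_trip_through_em(self):
        """Simulated haplotype pairs give back the target D' via ld_em."""
        target = 0.99
        specs = [gk.VariantSpec(snp_id="a", control_raf=0.22),
                 gk.VariantSpec(snp_id="b", control_raf=0.04)]
        cfg = gk.CohortSimConfig(variants=specs,
                                 per_allele_or={"a": 1.0, "b": 1.0},
                                 n_case=100, n_control=8000, prevalence=0.01,
                                 ld_pairs=[("a", "b", target)], seed=99)
        gm, ph = gk.simulate_cohort(cfg)
        res = gk.ld_em(*gm.column("a")[:1], *gm.column("b")[:1])
        assert res.d_prime == pytest.approx(target, abs=0.05)


class TestStratumFrequencies:
    def test_null_or_returns_hwe(self):
        g = gk.expected_genotype_freq_in_stratum(0.3, 1.0, -2.0, "case")
        assert np.allclose(g, [0.49, 0.42, 0.09])

    def test_normalization_random_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = gk.expected_genotype_freq_in_stratum(
                rng.uniform(0.01, 0.99), rng.uniform(0.2, 5.0),
                rng.uniform(-8, 0), rng.choice(["case", "control"]))
            assert g.sum() == pytest.approx(1.0)
            assert (g >= 0).all()

    def test_matches_empirical_case_frequencies(self):
        """Bayes-inverted case genotype law vs 1e5 prospective draws."""
        raf, or_, prev = 0.02, 5.2, 0.005
        cfg = _single_snp_config(raf=raf, or_=or_, prevalence=prev)
        b0 = gk.calibrate_intercept(cfg)
        expected = gk.expected_genotype_freq_in_stratum(raf, or_, b0, "case")
        rng = np.random.default_rng(42)
        n = 100_000
        dosage = rng.binomial(2, raf, n)
        is_case = rng.random(n) < expit(b0 + math.log(or_) * dosage)
        cases = dosage[is_case]
        emp = np.array([(cases == c).mean() for c in range(3)])
        se = np.sqrt(expected * (1 - expected) / cases.size)
        assert (np.abs(emp - expected) <= 3 * se + 1e-12).all()


class TestSimulateCohort:
    def test_quotas_and_determinism(self, tmp_path):
        cfg = _single_snp_config(seed=11)
        gm1, ph1 = gk.simulate_cohort(cfg)
        gm2, ph2 = gk.simulate_cohort(cfg)
        assert ph1.n_case == 50 and ph1.n_control == 50
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        gm1.to_tsv(p1)
        gm2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_null_model_strata_frequencies_agree(self):
        """With OR 1 the case/control frequency gap is sampling noise only."""
        diffs, ses = [], []
        for seed in range(20):
            cfg = _single_snp_config(or_=1.0, raf=0.3, prevalence=0.1,
                                     seed=seed, n_case=150, n_control=150)
            gm, ph = gk.simulate_cohort(cfg)
            cases, controls = gk.split_by_status(gm, ph)
            f1 = gk.allele_frequency(cases, "s")
            f0 = gk.allele_frequency(controls, "s")
            diffs.append(f1 - f0)
            ses.append(math.sqrt(2 * 0.3 * 0.7 / 300))
        # not every replicate must stay within 3 SE, but nearly all should
        frac = np.mean([abs(d) < 3 * s for d, s in zip(diffs, ses)])
        assert frac >= 0.95

    def test_prevalence_recovery_diagnostics(self):
        cfg = _single_snp_config(raf=0.3, or_=2.0, prevalence=0.1, seed=3,
                                 n_case=300, n_control=300)
        _, _, diag = gk.simulate_cohort(cfg, return_diagnostics=True)
        n = diag["total_draws"]
        se = math.sqrt(0.1 * 0.9 / n)
        assert abs(diag["observed_prevalence"] - 0.1) < 3 * se

    def test_extreme_prevalence_draw_cap(self):
        cfg = _single_snp_config(prevalence=1e-6, n_case=1000,
                                 max_total_draws=10_000)
        with pytest.raises(RuntimeError, match="cap"):
            gk.simulate_cohort(cfg)

    def test_allelic_or_recovery_and_ci_coverage(self):
        """Median allelic OR near truth; Wald CIs cover at ~95%."""
        truth = 3.0
        covered, ors = [], []
        for seed in range(200):
            cfg = _single_snp_config(raf=0.10, or_=truth, prevalence=0.005,
                                     seed=seed, n_case=369, n_control=503)
            gm, ph = gk.simulate_cohort(cfg)
            res = gk.allelic_test(gk.allelic_table(gm, ph, "s"))
            ors.append(res.or_point)
            covered.append(res.ci_low <= truth <= res.ci_high)
        assert abs(np.median(ors) - truth) / truth < 0.10
        assert 0.93 <= np.mean(covered) <= 0.97


class TestReferenceCohort:
    def test_sizes_and_control_frequency(self):
        gm, ph = gk.make_reference_cohort(seed=123)
        assert ph.n_case == 369 and ph.n_control == 503
        _, controls = gk.split_by_status(gm, ph)
        f = gk.allele_frequency(controls, "rs2066847")
        se = math.sqrt(0.02 * 0.98 / (2 * 503))
        assert abs(f - 0.02) <= 3 * se

    def test_same_seed_identical_output(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        gk.make_reference_cohort(seed=5)[0].to_tsv(a)
        gk.make_reference_cohort(seed=5)[0].to_tsv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_ld_cycle_rejected(self):
        specs = gk.full_panel()
        with pytest.raises(ValueError, match="cycle"):
            gk.CohortSimConfig(
                variants=specs, per_allele_or=gk.univariate_ors(),
                n_case=10, n_control=10,
                ld_pairs=[("rs13361189", "rs11747270", 0.9),
                          ("rs11747270", "rs1000113", 0.9),
                          ("rs1000113", "rs13361189", 0.9)])
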