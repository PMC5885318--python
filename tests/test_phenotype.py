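import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chisquare, kstest

from phewas_power.assoc import fit_linear_additive
from phewas_power.genotype import hwe_genotype_probs
from phewas_power.phenotype import (
    BinaryCohort,
    PenetranceFunction,
    QuantCohort,
    expected_case_genotype_dist,
    expected_control_genotype_dist,
    expected_prevalence,
    liability_effect_size,
    make_noise_phenotype,
    penetrance_table,
    sample_case_control,
    sample_quantitative,
)


class TestPenetranceTable:
    @pytest.mark.parametrize(
        "baseline, penetrance, expected",
        [
            (0.1, 0.3, (0.10, 0.20, 0.30)),
            (0.1, 0.1, (0.10, 0.10, 0.10)),
            (0.1, 0.15, (0.10, 0.125, 0.15)),
        ],
    )
    def test_additive_risk_midpoint(self, baseline, penetrance, expected):
        pf = penetrance_table(baseline, penetrance)
        assert (pf.f0, pf.f1, pf.f2) == pytest.approx(expected, abs=1e-12)

    def test_protective_coding_rejected(self):
        with pytest.raises(ValueError):
            penetrance_table(0.2, 0.1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            penetrance_table(0.1, 0.3, mode="multiplicative")

    def test_non_monotone_triple_rejected(self):
        with pytest.raises(ValueError):
            PenetranceFunction(0.3, 0.2, 0.1)


class TestExpectedDistributions:
    def test_marginal_prevalence_by_enumeration(self):
        pf = penetrance_table(0.1, 0.3)
        # 0.9025*0.1 + 0.095*0.2 + 0.0025*0.3
        assert expected_prevalence(pf, 0.05) == pytest.approx(0.11, abs=1e-12)

    def test_case_distribution_bayes_enumeration(self):
        pf = penetrance_table(0.1, 0.3)
        dist = expected_case_genotype_dist(pf, 0.05)
        assert dist == pytest.approx((0.82045, 0.17273, 0.00682), abs=5e-6)

    def test_flat_penetrance_recovers_hwe(self):
        pf = PenetranceFunction(1.0, 1.0, 1.0)
        assert expected_case_genotype_dist(pf, 0.3) == pytest.approx(
            hwe_genotype_probs(0.3), abs=1e-12
        )

    def test_fully_penetrant_homozygote_only(self):
        pf = PenetranceFunction(0.0, 0.0, 1.0)
        assert expected_case_genotype_dist(pf, 0.05) == pytest.approx((0, 0, 1), abs=1e-12)

    def test_zero_mass_raises(self):
        pf = PenetranceFunction(0.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            expected_case_genotype_dist(pf, 0.0)  # maf=0: only genotype 0, risk 0


class TestCaseControlSampler:
    def test_worked_example_counts(self, rng):
        """10 cases and 20 controls at ratio 1:2, cases first."""
        pf = penetrance_table(0.1, 0.15)
        cohort = sample_case_control(pf, 0.01, 10, 2, rng)
        assert cohort.n_cases == 10 and cohort.n_controls == 20
        assert cohort.status.sum() == 10
        assert len(cohort.genotypes) == 30
        assert cohort.status[:10].all() and not cohort.status[10:].any()

    @pytest.mark.parametrize(
        "baseline, penetrance, maf",
        [(0.1, 0.3, 0.05), (0.1, 0.15, 0.25), (0.1, 0.2, 0.1)],
    )
    def test_strata_match_bayes_enumeration(self, baseline, penetrance, maf):
        """Case and control genotype distributions follow HWE*f / HWE*(1-f)."""
        rng = np.random.default_rng(int(penetrance * 1000) + int(maf * 100))
        pf = penetrance_table(baseline, penetrance)
        cohort = sample_case_control(pf, maf, 10**5, 1, rng)
        cases = cohort.genotypes[cohort.status == 1]
        ctrls = cohort.genotypes[cohort.status == 0]
        for stratum, expected in (
            (cases, expected_case_genotype_dist(pf, maf)),
            (ctrls, expected_control_genotype_dist(pf, maf)),
        ):
            observed = np.bincount(stratum, minlength=3)
            exp_counts = np.asarray(expected) * stratum.size
            keep = exp_counts > 0
            assert chisquare(observed[keep], exp_counts[keep]).pvalue > 0.001

    def test_null_penetrance_keeps_strata_at_hwe(self):
        """f0=f1=f2: status independent of genotype, both strata are HWE."""
        rng = np.random.default_rng(99)
        pf = penetrance_table(0.1, 0.1)
        cohort = sample_case_control(pf, 0.25, 40000, 1, rng)
        hwe = np.asarray(hwe_genotype_probs(0.25))
        for stratum in (cohort.genotypes[cohort.status == 1], cohort.genotypes[cohort.status == 0]):
            observed = np.bincount(stratum, minlength=3)
            assert chisquare(observed, hwe * stratum.size).pvalue > 0.001

    def test_degenerate_quota_raises_after_cap(self, rng):
        pf = PenetranceFunction(0.0, 0.0, 0.0)
        with pytest.raises(RuntimeError):
            sample_case_control(pf, 0.1, 5, 1, rng, draw_cap=2000)

    def test_invalid_arguments(self, rng):
        pf = penetrance_table(0.1, 0.2)
        with pytest.raises(ValueError):
            sample_case_control(pf, 0.1, 0, 2, rng)
        with pytest.raises(ValueError):
            sample_case_control(pf, 0.1, 10, 0.5, rng)


class TestLiabilityEffectSize:
    @pytest.mark.parametrize(
        "baseline, penetrance, expected",
        [
            (0.1, 0.3, (1.2815515655 - 0.5244005127) / 2),
            (0.1, 0.1, 0.0),
            (0.1, 0.15, (1.2815515655 - 1.0364333895) / 2),
        ],
    )
    def test_normal_quantile_arithmetic(self, baseline, penetrance, expected):
        assert liability_effect_size(baseline, penetrance) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("baseline, penetrance", [(0.0, 0.5), (0.1, 1.0), (1.0, 1.0)])
    def test_domain_errors(self, baseline, penetrance):
        with pytest.raises(ValueError):
            liability_effect_size(baseline, penetrance)

    @given(
        pen=st.floats(0.101, 0.99),
        pen_hi=st.floats(0.0001, 0.009),
    )
    def test_monotone_in_penetrance(self, pen, pen_hi):
        lo = liability_effect_size(0.1, pen)
        hi = liability_effect_size(0.1, min(pen + pen_hi, 0.999))
        assert hi >= lo
        assert lo > 0  # zero only at penetrance == baseline

    def test_threshold_calibration(self):
        """beta is calibrated so P(Y > Phi^-1(1-f0) | g) hits f0 and f2."""
        from scipy.stats import norm

        beta = liability_effect_size(0.1, 0.3)
        thr = norm.ppf(0.9)
        assert norm.sf(thr - 0 * beta) == pytest.approx(0.1, abs=1e-12)
        assert norm.sf(thr - 2 * beta) == pytest.approx(0.3, abs=1e-9)


class TestQuantitativeSampler:
    def test_slope_recovered_at_large_n(self):
        rng = np.random.default_rng(5)
        beta = liability_effect_size(0.1, 0.3)
        cohort = sample_quantitative(beta, 0.25, 10**5, rng)
        fit = fit_linear_additive(cohort.genotypes, cohort.trait)
        assert abs(fit.beta - beta) < 4 * fit.se

    def test_monomorphic_genotype_gives_pure_noise(self):
        rng = np.random.default_rng(6)
        cohort = sample_quantitative(0.5, 0.0, 10**5, rng)
        assert not cohort.genotypes.any()
        assert kstest(cohort.trait, "norm").pvalue > 0.001

    def test_residuals_standard_normal(self):
        """Residuals about the genotype-group means are N(0, 1)."""
        rng = np.random.default_rng(7)
        beta = liability_effect_size(0.1, 0.3)
        cohort = sample_quantitative(beta, 0.25, 10**5, rng)
        resid = cohort.trait - beta * cohort.genotypes
        assert kstest(resid, "norm").pvalue > 0.001

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_quantitative(0.1, 0.25, 1, rng)


class TestNoisePhenotype:
    def test_binary_noise_preserves_counts(self, rng):
        status = np.zeros(30, dtype=np.int8)
        status[:10] = 1
        cohort = BinaryCohort(np.zeros(30, dtype=np.int8), status, 10, 20)
        noise = make_noise_phenotype(cohort, rng)
        assert noise.sum() == 10 and noise.size == 30

    def test_distinct_substreams_give_distinct_permutations(self, rng):
        status = np.zeros(200, dtype=np.int8)
        status[:100] = 1
        cohort = BinaryCohort(np.zeros(200, dtype=np.int8), status, 100, 100)
        a = make_noise_phenotype(cohort, rng)
        b = make_noise_phenotype(cohort, rng)
        assert not np.array_equal(a, b)

    def test_quantitative_noise_is_fresh_normal(self, rng):
        cohort = QuantCohort(np.zeros(5000, dtype=np.int8), np.ones(5000))
        noise = make_noise_phenotype(cohort, rng)
        assert noise.size == 5000
        assert kstest(noise, "norm").pvalue > 0.001

    def test_unsupported_template_rejected(self, rng):
        with pytest.raises(TypeError):
            make_noise_phenotype([0, 1, 1], rng)
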