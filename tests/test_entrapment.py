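import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from superfill.entrapment import (
    GaussianFluctuationModel,
    OccupancyCounts,
    PoissonNull,
    PowerLawOccupancy,
    coentrapment_probability,
    compare_occupancy_models,
    critical_factor,
    fit_powerlaw_exponent,
    gaussian_exceedance,
    gaussian_table,
    log10_gaussian_exceedance,
    poisson_pmf,
    powerlaw_pmf,
    prob_at_least,
    sample_occupancies,
)


class TestPoissonNull:
    def test_pmf_values(self):
        m = PoissonNull(2.0)
        assert poisson_pmf(0, m) == pytest.approx(math.exp(-2), rel=1e-12)
        assert poisson_pmf(2, m) == pytest.approx(math.exp(-2) * 2, rel=1e-12)

    def test_pmf_normalizes_even_for_large_mu(self):
        # at mu = 1e6 the bound reflects the pmf evaluation accuracy
        # (~5e-10 summed over 4e4 terms), not truncation of the support
        for mu, deficit in ((2.0, 1e-10), (1e3, 1e-10), (1e6, 1e-8)):
            m = PoissonNull(mu)
            hi = int(mu + 20 * math.sqrt(mu) + 50)
            lo = max(0, int(mu - 20 * math.sqrt(mu) - 50))
            total = poisson_pmf(np.arange(lo, hi), m).sum()
            assert total > 1 - deficit

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            poisson_pmf(-1, PoissonNull(2.0))

    def test_prob_at_least(self):
        assert prob_at_least(0, PoissonNull(5.0)) == 1.0
        assert prob_at_least(1, PoissonNull(0.5)) == pytest.approx(
            1 - math.exp(-0.5), rel=1e-12
        )
        assert prob_at_least(1, PoissonNull(1e-12)) == pytest.approx(0.0, abs=1e-11)


class TestCoentrapment:
    def test_single_species_equals_marginal(self):
        res = coentrapment_probability([0.5], [1])
        assert res.probability == pytest.approx(prob_at_least(1, PoissonNull(0.5)), rel=1e-12)

    def test_three_species_product_rule(self):
        res = coentrapment_probability([0.5] * 3, [1] * 3)
        assert res.probability == pytest.approx((1 - math.exp(-0.5)) ** 3, rel=1e-10)

    def test_many_species_stays_finite_in_log_space(self):
        """Capturing 80 species at once from a dilute solution: the
        probability underflows intuition but not the log10 report."""
        res = coentrapment_probability([0.5] * 80, [1] * 80)
        expected_log10 = 80 * math.log10(1 - math.exp(-0.5))
        assert res.log10_probability == pytest.approx(expected_log10, rel=1e-10)
        assert res.log10_probability == pytest.approx(-32.4, abs=0.1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            coentrapment_probability([1.0, 2.0], [1])


class TestGaussianFluctuations:
    def test_median_tail_is_half(self):
        m = GaussianFluctuationModel(32, 5.6)
        assert gaussian_exceedance(m, 1.0) == pytest.approx(0.5, rel=1e-12)

    def test_double_concentration_is_vanishingly_rare(self):
        m = GaussianFluctuationModel(32, 5.6)
        # independent oracle: normal survival function
        assert gaussian_exceedance(m, 2.0) == pytest.approx(
            stats.norm.sf(2.0, loc=1.0, scale=5.6 / 32), rel=1e-9
        )
        assert gaussian_exceedance(m, 2.0) == pytest.approx(5.5e-9, rel=0.01)
        assert gaussian_exceedance(m, 2.4) == pytest.approx(6.2e-16, rel=0.01)

    def test_log10_tail_consistent_and_deep(self):
        m = GaussianFluctuationModel(32, 5.6)
        assert 10 ** log10_gaussian_exceedance(m, 2.0) == pytest.approx(
            gaussian_exceedance(m, 2.0), rel=1e-9
        )
        # far past double underflow the log form still works
        assert log10_gaussian_exceedance(m, 10.0) < -280

    def test_monte_carlo_agreement_in_moderate_tail(self):
        m = GaussianFluctuationModel(32, 5.6)
        rng = np.random.default_rng(7)
        draws = rng.normal(m.n0, m.delta_n, size=10_000_000)
        for r in (1.1, 1.3, 1.5):
            p = gaussian_exceedance(m, r)
            p_mc = np.mean(draws > r * m.n0)
            mc_sd = math.sqrt(p * (1 - p) / len(draws))
            assert abs(p_mc - p) < 3 * mc_sd + 1e-12

    def test_exceedance_decreases_in_r(self):
        m = GaussianFluctuationModel(32, 5.6)
        rs = np.linspace(0.5, 3.0, 30)
        vals = [gaussian_exceedance(m, r) for r in rs]
        assert np.all(np.diff(vals) < 0)

    def test_from_poisson_sets_sqrt_sd(self):
        g = GaussianFluctuationModel.from_poisson(PoissonNull(32.0))
        assert g.delta_n == pytest.approx(math.sqrt(32), rel=1e-12)

    def test_poisson_and_gaussian_tails_agree_in_normal_regime(self):
        """In the few-tens-of-molecules regime the Poisson upper tail and
        its Gaussian approximation differ by less than a factor 2 up to
        r = 1.5.  (Deeper tails at much larger mu diverge relatively —
        the normal approximation is a local, not a large-deviation,
        statement.)"""
        for mu in (30.0, 32.0, 50.0):
            g = GaussianFluctuationModel(mu, math.sqrt(mu))
            for r in (1.1, 1.3, 1.5):
                p_pois = stats.poisson.sf(math.floor(r * mu), mu)
                p_gauss = gaussian_exceedance(g, r)
                assert 0.5 < p_pois / p_gauss < 2.0


class TestCriticalFactor:
    def test_median(self):
        m = GaussianFluctuationModel(32, 5.6)
        assert critical_factor(m, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_one_percent_tail_factor(self):
        """99% of a passively filled population concentrates < 1.41x."""
        mu = 31.5
        m = GaussianFluctuationModel(mu, math.sqrt(mu))
        assert critical_factor(m, 0.01) == pytest.approx(1.41, abs=0.005)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-12, max_value=1 - 1e-6))
    def test_inverse_of_exceedance(self, p):
        m = GaussianFluctuationModel(32, 5.6)
        r = critical_factor(m, p)
        assert gaussian_exceedance(m, r) == pytest.approx(p, rel=1e-8)

    def test_decreasing_in_p_and_domain(self):
        m = GaussianFluctuationModel(32, 5.6)
        ps = [0.001, 0.01, 0.1, 0.5, 0.9]
        rs = [critical_factor(m, p) for p in ps]
        assert np.all(np.diff(rs) < 0)
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                critical_factor(m, bad)


class TestPowerLaw:
    def test_zero_exponent_is_uniform(self):
        m = PowerLawOccupancy(exponent=0.0, n_min=2, n_max=5)
        vals = powerlaw_pmf(np.arange(2, 6), m)
        assert np.allclose(vals, 0.25)

    def test_harmonic_normalization(self):
        m = PowerLawOccupancy(exponent=1.0, n_min=1, n_max=3)
        assert powerlaw_pmf(1, m) == pytest.approx(6 / 11, rel=1e-10)

    def test_pmf_sums_to_one_with_empty_mass(self):
        m = PowerLawOccupancy(exponent=1.5, n_min=1, n_max=500, empty_mass=0.7)
        total = powerlaw_pmf(np.arange(0, 501), m).sum()
        assert total == pytest.approx(1.0, abs=1e-10)
        assert powerlaw_pmf(0, m) == pytest.approx(0.7)

    def test_off_support_is_zero_not_error(self):
        m = PowerLawOccupancy(exponent=1.5, n_min=2, n_max=10)
        assert powerlaw_pmf(1, m) == 0.0
        assert powerlaw_pmf(11, m) == 0.0


class TestSampling:
    def test_poisson_sample_mean_clt(self):
        counts = sample_occupancies(PoissonNull(5.0), 100_000, seed=11)
        mean = np.average(counts.occupancies, weights=counts.counts)
        assert abs(mean - 5.0) < 3 * math.sqrt(5.0 / 100_000)

    def test_seed_determinism(self):
        a = sample_occupancies(PoissonNull(3.0), 1000, seed=5)
        b = sample_occupancies(PoissonNull(3.0), 1000, seed=5)
        assert np.array_equal(a.occupancies, b.occupancies)
        assert np.array_equal(a.counts, b.counts)

    def test_powerlaw_sample_respects_support(self):
        m = PowerLawOccupancy(exponent=1.5, n_min=3, n_max=100)
        counts = sample_occupancies(m, 5000, seed=2)
        assert counts.occupancies.min() >= 3
        assert counts.occupancies.max() <= 100

    def test_sampler_matches_pmf_chisquare(self):
        """Seeded sampler frequencies agree with the generating pmf."""
        mu = 5.0
        counts = sample_occupancies(PoissonNull(mu), 100_000, seed=13)
        support = np.arange(0, 16)
        expected = poisson_pmf(support, PoissonNull(mu)) * counts.total
        observed = np.zeros(len(support))
        for n, c in zip(counts.occupancies, counts.counts):
            observed[min(n, 15)] += c
        expected[-1] = counts.total - expected[:-1].sum()
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001


class TestPowerLawFit:
    @pytest.mark.parametrize("a_true", [1.2, 1.5, 2.0])
    def test_recovers_exponent_within_three_se(self, a_true):
        m = PowerLawOccupancy(exponent=a_true, n_min=1, n_max=10_000)
        counts = sample_occupancies(m, 10_000, seed=42)
        fit = fit_powerlaw_exponent(counts, n_min=1, n_max=10_000)
        assert abs(fit.exponent - a_true) < 3 * fit.stderr

    def test_count_scale_invariance(self):
        m = PowerLawOccupancy(exponent=1.5, n_min=1, n_max=1000)
        counts = sample_occupancies(m, 2000, seed=3)
        doubled = OccupancyCounts(counts.occupancies, counts.counts * 2)
        f1 = fit_powerlaw_exponent(counts, n_max=1000)
        f2 = fit_powerlaw_exponent(doubled, n_max=1000)
        assert f2.exponent == pytest.approx(f1.exponent, abs=1e-6)

    def test_insufficient_and_degenerate_data(self):
        with pytest.raises(ValueError):
            fit_powerlaw_exponent(OccupancyCounts([1, 2], [3, 2]))
        with pytest.raises(ValueError):
            fit_powerlaw_exponent(OccupancyCounts([5], [100]))


class TestModelComparison:
    def test_poisson_data_prefers_poisson(self):
        """On Poisson-generated samples the Poisson log-likelihood wins
        essentially always against a generic power law."""
        wins = 0
        poisson = PoissonNull(5.0)
        powerlaw = PowerLawOccupancy(exponent=1.5, n_min=1, n_max=1000, empty_mass=0.01)
        for seed in range(100):
            counts = sample_occupancies(poisson, 10_000, seed=seed)
            rep = compare_occupancy_models(counts, poisson, powerlaw)
            wins += rep["loglik_poisson"] >= rep["loglik_powerlaw"]
        assert wins >= 95

    def test_powerlaw_data_shows_superfilled_excess(self):
        powerlaw = PowerLawOccupancy(exponent=1.2, n_min=1, n_max=1000, empty_mass=0.3)
        counts = sample_occupancies(powerlaw, 10_000, seed=9)
        mean = np.average(counts.occupancies, weights=counts.counts)
        rep = compare_occupancy_models(counts, PoissonNull(mean), powerlaw)
        assert rep["superfilled_fraction"] > rep["poisson_expected_superfilled_fraction"]
        assert rep["preferred"] == "powerlaw"

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            OccupancyCounts([], [])


class TestGaussianTable:
    def test_canonical_rows(self):
        m = GaussianFluctuationModel(32, 5.6)
        table = gaussian_table(m)
        assert list(table["r"]) == [1.0, 1.41, 2.0, 2.4]
        assert list(table["threshold_count"]) == pytest.approx([32, 45.12, 64, 76.8])
        assert table["tail_percent"].iloc[0] == pytest.approx(50.0)
        assert table["tail_percent"].iloc[2] <= 1e-6
        assert table["tail_percent"].iloc[3] <= 1e-13
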