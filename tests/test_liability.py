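"""Probit liability model: risk map, induced distribution, simulation."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import integrate, special
from scipy.stats import norm

import ginirisk as gr
from ginirisk.exceptions import ParameterDomainError

PROSTATE = gr.LiabilityModelParams(h2=0.57, lifetime_risk=0.105)
OVERALL = gr.LiabilityModelParams(h2=0.33, lifetime_risk=0.324)


def mz_concordance_oracle(h2, lifetime_risk):
    """P(both MZ twins affected) from the bivariate-normal orthant.

    The twins' liabilities are standard normal with correlation h2, so the
    concordance is Phi2(-t, -t; rho=h2) with t the liability threshold,
    evaluated through Owen's T function — a route independent of the
    risk-distribution quadrature it checks.
    """
    t = norm.ppf(1.0 - lifetime_risk)
    a = np.sqrt((1.0 - h2) / (1.0 + h2))
    return norm.cdf(-t) - 2.0 * special.owens_t(-t, a)


class TestRiskMap:
    def test_risk_at_threshold_liability_is_half(self):
        for params in (PROSTATE, OVERALL):
            assert gr.risk_given_genetic_liability(
                params.threshold, params
            ) == pytest.approx(0.5, abs=1e-12)

    def test_average_genotype_risk_closed_form(self):
        # Phi(-Phi^{-1}(0.895)/sqrt(0.43)) evaluated from normal tables
        assert gr.risk_given_genetic_liability(0.0, PROSTATE) == pytest.approx(
            0.0279, abs=1e-4
        )

    def test_strictly_increasing_in_liability(self):
        assert gr.risk_given_genetic_liability(
            -1.0, PROSTATE
        ) < gr.risk_given_genetic_liability(1.0, PROSTATE)

    def test_median_risk_inverts_to_threshold(self):
        assert gr.genetic_liability_given_risk(0.5, PROSTATE) == pytest.approx(
            PROSTATE.threshold, abs=1e-12
        )

    def test_inverse_roundtrip(self):
        iota = np.arange(-3.0, 3.5, 1.0)
        y = gr.risk_given_genetic_liability(iota, PROSTATE)
        back = gr.genetic_liability_given_risk(y, PROSTATE)
        np.testing.assert_allclose(back, iota, atol=1e-10)

    def test_average_genotype_example_inverts_to_zero(self):
        assert gr.genetic_liability_given_risk(0.0279, PROSTATE) == pytest.approx(
            0.0, abs=1e-2
        )

    @given(
        h2=st.floats(0.05, 0.95),
        risk=st.floats(0.01, 0.9),
        iota=st.floats(-4.0, 4.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_roundtrip_property(self, h2, risk, iota):
        params = gr.LiabilityModelParams(h2=h2, lifetime_risk=risk)
        y = gr.risk_given_genetic_liability(iota, params)
        assert 0.0 <= y <= 1.0
        # near the interval ends the float spacing of Phi limits how much
        # liability precision survives the roundtrip; stay in the interior
        assume(1e-8 < y < 1.0 - 1e-8)
        assert gr.genetic_liability_given_risk(y, params) == pytest.approx(
            iota, abs=1e-6
        )

    @pytest.mark.parametrize("bad", [-0.1, 0.0, 1.0, 1.5])
    def test_invalid_heritability_rejected(self, bad):
        if bad == 0.0:
            # admitted as the degenerate limit, but not as a probit model
            with pytest.raises(ParameterDomainError):
                gr.ProbitRiskDistribution(
                    gr.LiabilityModelParams(h2=0.0, lifetime_risk=0.1)
                )
        else:
            with pytest.raises(ParameterDomainError):
                gr.LiabilityModelParams(h2=bad, lifetime_risk=0.1)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_lifetime_risk_rejected(self, bad):
        with pytest.raises(ParameterDomainError):
            gr.LiabilityModelParams(h2=0.5, lifetime_risk=bad)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_risk_inverse_domain(self, bad):
        with pytest.raises(ParameterDomainError):
            gr.genetic_liability_given_risk(bad, PROSTATE)


class TestDistributionFunctions:
    def test_density_normalises(self, overall_cancer):
        total, _ = integrate.quad(overall_cancer.pdf, 0.0, 1.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_density_mean_is_lifetime_risk(self, overall_cancer):
        mean, _ = integrate.quad(
            lambda y: y * overall_cancer.pdf(y), 0.0, 1.0, limit=200
        )
        assert mean == pytest.approx(0.324, abs=1e-6)

    def test_quadrature_mean_identity(self, prostate):
        assert prostate.moment(1) == pytest.approx(prostate.mean, abs=1e-9)

    def test_cdf_quantile_inverse(self, prostate):
        for p in (0.05, 0.2, 0.5, 0.8, 0.95):
            assert prostate.cdf(prostate.quantile(p)) == pytest.approx(
                p, abs=1e-10
            )

    def test_median_is_average_genotype_risk(self, prostate):
        y_med = gr.risk_given_genetic_liability(0.0, prostate.params)
        assert prostate.cdf(y_med) == pytest.approx(0.5, abs=1e-12)
        assert prostate.quantile(0.5) == pytest.approx(y_med, abs=1e-12)

    def test_quantiles_strictly_increasing(self, prostate):
        probs = np.linspace(0.01, 0.99, 25)
        values = prostate.quantile(probs)
        assert np.all(np.diff(values) > 0.0)

    def test_cdf_is_antiderivative_of_pdf(self, prostate):
        # centred finite difference of F_Y against f_Y at interior points
        for y in (0.01, 0.05, 0.105, 0.3, 0.6):
            h = 1e-6
            deriv = (prostate.cdf(y + h) - prostate.cdf(y - h)) / (2 * h)
            assert deriv == pytest.approx(prostate.pdf(y), rel=1e-5)

    def test_pdf_cdf_domain_errors(self, prostate):
        for y in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ParameterDomainError):
                prostate.pdf(y)
            with pytest.raises(ParameterDomainError):
                prostate.cdf(y)
        with pytest.raises(ParameterDomainError):
            prostate.quantile(0.0)


class TestMoments:
    def test_variance_bounds(self, prostate):
        var = prostate.variance()
        mu = prostate.mean
        assert 0.0 < var < mu * (1.0 - mu)

    def test_variance_vanishes_without_genetic_variance(self):
        dist = gr.ProbitRiskDistribution(
            gr.LiabilityModelParams(h2=1e-6, lifetime_risk=0.2)
        )
        assert dist.variance() == pytest.approx(0.0, abs=1e-6)

    def test_second_moment_equals_mz_concordance(self, prostate):
        oracle = mz_concordance_oracle(0.57, 0.105)
        assert prostate.moment(2) == pytest.approx(oracle, abs=1e-9)

    def test_implied_lambda_from_concordance(self, overall_cancer):
        oracle = mz_concordance_oracle(0.33, 0.324) / 0.324**2
        assert overall_cancer.implied_lambda() == pytest.approx(oracle, abs=1e-7)

    def test_partial_mean_full_range_is_mean(self, prostate):
        assert prostate.partial_mean(1.0) == pytest.approx(
            prostate.mean, abs=1e-9
        )
        assert prostate.partial_mean(0.0) == 0.0


class TestSampler:
    def test_seed_reproducibility(self, prostate):
        a = prostate.sample(1000, seed=42)
        b = prostate.sample(1000, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, prostate.sample(1000, seed=43))

    def test_draws_inside_open_unit_interval(self, prostate):
        y = prostate.sample(10_000, seed=0)
        assert np.all((y > 0.0) & (y < 1.0))

    def test_sample_mean_matches_lifetime_risk(self, overall_cancer):
        n = 1_000_000
        y = overall_cancer.sample(n, seed=7)
        se = y.std(ddof=1) / np.sqrt(n)
        assert abs(y.mean() - 0.324) < 3.0 * se

    def test_sample_variance_matches_quadrature(self, prostate):
        n = 400_000
        y = prostate.sample(n, seed=11)
        centred_sq = (y - y.mean()) ** 2
        se = centred_sq.std(ddof=1) / np.sqrt(n)
        assert abs(y.var(ddof=1) - prostate.variance()) < 3.0 * se

    def test_empirical_cdf_within_dkw_band(self, prostate):
        n = 100_000
        y = np.sort(prostate.sample(n, seed=3))
        ecdf = np.arange(1, n + 1) / n
        theo = prostate.cdf(y)
        # Dvoretzky-Kiefer-Wolfowitz bound at alpha = 0.01
        eps = np.sqrt(np.log(2.0 / 0.01) / (2.0 * n))
        assert np.max(np.abs(ecdf - theo)) < eps

    def test_quantile_matches_simulated_share(self, prostate):
        n = 1_000_000
        y = prostate.sample(n, seed=5)
        share = np.mean(y < prostate.quantile(0.2))
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(share - 0.2) < 3.0 * se

    def test_pdf_matches_histogram(self, prostate):
        n = 1_000_000
        y = prostate.sample(n, seed=9)
        # compare bin probabilities, not raw density, to sidestep endpoint spikes
        edges = prostate.quantile(np.linspace(0.05, 0.95, 19))
        counts, _ = np.histogram(y, bins=edges)
        expected = np.diff(prostate.cdf(edges)) * n
        # each bin holds 5% of the mass: Poisson-scale fluctuations
        assert np.all(np.abs(counts - expected) < 4.0 * np.sqrt(expected))

    def test_rejects_empty_sample(self, prostate):
        with pytest.raises(ValueError):
            prostate.sample(0)


class TestDegenerateLimit:
    def test_zero_heritability_gives_point_mass(self):
        dist = gr.probit_risk_distribution(0.0, 0.2)
        assert isinstance(dist, gr.DegenerateRiskDistribution)
        assert dist.mean == 0.2
        assert dist.variance() == 0.0
        assert dist.quantile(0.3) == 0.2
        assert np.all(dist.sample(5, seed=1) == 0.2)

    def test_density_grid_covers_support(self, prostate):
        grid = gr.density_grid(prostate, n=64)
        assert grid.shape == (64, 2)
        assert np.all((grid[:, 0] > 0) & (grid[:, 0] < 1))
        assert np.all(grid[:, 1] >= 0)
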