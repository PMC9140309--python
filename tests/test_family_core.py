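import numpy as np
import pytest
from scipy import integrate, stats

from egug.baselines import make_baseline
from egug.egunh import EGuNHParams, egunh_pdf, egunh_quantile, to_family_params
from egug.family_core import (
    ExpansionCoefficients,
    FamilyParams,
    expansion_coefficients,
    family_cdf,
    family_chrf,
    family_hrf,
    family_pdf,
    family_quantile,
    family_sample,
    family_sf,
    order_stat_pdf,
    shape_diagnosis,
    stirling_polynomial,
)


def _params(theta, sigma, baseline=None):
    return FamilyParams(theta, sigma, baseline or make_baseline("weibull", a=1.0, b=1.5))


class TestCdf:
    def test_support_endpoints(self, nh_family):
        assert float(family_cdf(0.0, nh_family)) == 0.0
        assert float(family_cdf(1e15, nh_family)) == pytest.approx(1.0, abs=1e-12)

    def test_printed_median_anchor(self):
        """At (theta, sigma, alpha) = (2.1, 0.29, 1.5) the median is 0.310.

        0.310 is the 3-decimal rounding of the true median, so the cdf there
        is 0.500 up to the local density times half a rounding step.
        """
        p = FamilyParams(2.1, 0.29, make_baseline("nh", alpha=1.5, lam=1.0))
        tol = 5e-4 * float(family_pdf(0.310, p)) + 1e-6
        assert float(family_cdf(0.310, p)) == pytest.approx(0.500, abs=tol)

    def test_nondecreasing_across_shape_grid(self, shape_grid):
        for theta, sigma in shape_grid:
            p = _params(theta, sigma)
            x = np.geomspace(1e-6, 100, 1000)
            assert np.all(np.diff(family_cdf(x, p)) >= -1e-15), (theta, sigma)

    def test_theta_one_reduction(self):
        """For theta=1 the cdf collapses to 1 - exp{-(-log Z)^(-1/sigma)}."""
        b = make_baseline("weibull", a=0.7, b=1.2)
        p = FamilyParams(1.0, 0.8, b)
        x = np.geomspace(0.05, 20, 50)
        direct = 1.0 - np.exp(-((-np.log(b.cdf(x))) ** (-1.0 / 0.8)))
        assert np.max(np.abs(family_cdf(x, p) - direct)) < 1e-12


class TestPdf:
    def test_normalizes(self, shape_grid):
        """Integrated density plus the unreached tail mass equals 1.

        Several shape combinations put probability at x-scales spanning
        hundreds of orders of magnitude, so the integral runs in log-x space
        between representable quantiles and the cdf supplies the mass outside
        that window.
        """
        from helpers import integrated_mass

        for theta, sigma in shape_grid[::2]:
            p = _params(theta, sigma)
            assert integrated_mass(p) == pytest.approx(1.0, abs=1e-6), (theta, sigma)

    def test_matches_cdf_derivative(self, nh_family):
        xs = family_quantile(np.linspace(0.05, 0.95, 10), nh_family)
        for x in xs:
            h = 1e-6 * max(x, 1e-3)
            num = (family_cdf(x + h, nh_family) - family_cdf(x - h, nh_family)) / (2 * h)
            assert float(family_pdf(x, nh_family)) == pytest.approx(float(num), rel=1e-6)

    def test_agrees_with_special_model(self, nh_params, nh_family):
        x = np.linspace(0.02, 3.0, 20)
        assert np.max(np.abs(family_pdf(x, nh_family) - egunh_pdf(x, nh_params))) < 1e-12

    def test_nonnegative(self, shape_grid):
        for theta, sigma in shape_grid:
            p = _params(theta, sigma)
            assert np.all(family_pdf(np.geomspace(1e-6, 50, 200), p) >= 0.0)


class TestHazardIdentities:
    def test_sf_complements_cdf(self, nh_family):
        x = np.geomspace(0.01, 5, 100)
        assert np.max(np.abs(family_sf(x, nh_family) + family_cdf(x, nh_family) - 1)) < 1e-15

    def test_chrf_is_log_sf(self, nh_family):
        x = family_quantile(np.linspace(0.01, 0.999, 100), nh_family)
        assert np.allclose(family_chrf(x, nh_family), -np.log(family_sf(x, nh_family)))

    def test_hrf_times_sf_is_pdf(self, nh_family):
        # stay where sf is representable: the right tail dies doubly
        # exponentially and sf underflows shortly past the 0.999 quantile
        x = family_quantile(np.linspace(0.05, 0.999, 50), nh_family)
        lhs = family_hrf(x, nh_family) * family_sf(x, nh_family)
        rhs = family_pdf(x, nh_family)
        assert np.max(np.abs(lhs - rhs) / rhs) < 1e-10

    def test_hrf_raises_when_sf_underflows(self, nh_family):
        with pytest.raises(FloatingPointError):
            family_hrf(1e9, nh_family)


class TestQuantile:
    def test_round_trip_u_grid(self, shape_grid):
        # quantiles below the double-precision floor come back as exactly 0
        # and cannot round-trip; every representable point must pass
        u = np.concatenate([[1e-6], np.linspace(0.01, 0.99, 99), [1 - 1e-6]])
        for theta, sigma in shape_grid:
            p = _params(theta, sigma)
            q = family_quantile(u, p)
            mask = q > 0.0
            assert mask.sum() >= 20, (theta, sigma)
            err = np.abs(family_cdf(q[mask], p) - u[mask])
            assert np.max(err) < 1e-9, (theta, sigma)

    def test_round_trip_full_grid_on_anchor_set(self, nh_family):
        u = np.concatenate([[1e-6], np.linspace(0.01, 0.99, 99), [1 - 1e-6]])
        err = np.abs(family_cdf(family_quantile(u, nh_family), nh_family) - u)
        assert np.max(err) < 1e-9

    def test_printed_median_second_row(self):
        p = FamilyParams(6.5, 0.33, make_baseline("nh", alpha=1.35, lam=1.0))
        assert float(family_quantile(0.5, p)) == pytest.approx(0.436, abs=5e-4)

    def test_agrees_with_closed_form(self, nh_params, nh_family):
        u = np.linspace(0.01, 0.99, 50)
        diff = np.abs(family_quantile(u, nh_family) - egunh_quantile(u, nh_params))
        assert np.max(diff) < 1e-10

    def test_rejects_boundary_u(self, nh_family):
        for u in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                family_quantile(u, nh_family)


class TestSampling:
    def test_reproducible(self, nh_family):
        a = family_sample(100, nh_family, seed=7)
        b = family_sample(100, nh_family, seed=7)
        assert np.array_equal(a, b)

    def test_ks_against_cdf(self, nh_family):
        x = family_sample(10_000, nh_family, seed=11)
        res = stats.kstest(x, lambda t: family_cdf(t, nh_family))
        assert res.pvalue > 0.01

    def test_draws_inside_support(self, nh_family):
        x = family_sample(1000, nh_family, seed=3)
        lo, hi = nh_family.baseline.support
        assert np.all((x > lo) & (x < hi))


class TestExpansion:
    def test_stirling_values(self):
        assert stirling_polynomial(0, 12.3) == 0.5
        assert stirling_polynomial(1, 1.0) == pytest.approx(1.0 / 3.0)
        assert stirling_polynomial(2, 2.0) == pytest.approx(5.0 / 6.0)

    def test_stirling_unsupported_order(self):
        with pytest.raises(ValueError, match="unsupported order"):
            stirling_polynomial(3, 1.0)

    def test_coefficients_finite_and_flagged(self, nh_family):
        coef = expansion_coefficients(nh_family, 25)
        assert isinstance(coef, ExpansionCoefficients)
        assert len(coef.pi_m) == 25
        assert np.all(np.isfinite(coef.pi_m))
        # non-convergence must be reported via the flag, never raised
        assert isinstance(coef.converged, bool)

    def test_reconstruction_contract(self, nh_family):
        """A convergence claim must be backed by cdf reconstruction.

        The formal series has no convergence guarantee; the contract is an
        implication: whenever the flag reports convergence the partial sums
        sum_m Pi_m Z(x)^m must reproduce the cdf, and a divergent series must
        be reported as such (finite coefficients, flag False, no exception).
        """
        coef = expansion_coefficients(nh_family, 40)
        x = np.linspace(0.1, 1.5, 5)
        Z = nh_family.baseline.cdf(x)
        recon = np.array([np.sum(coef.pi_m * Z_i ** np.arange(1, 41)) for Z_i in Z])
        if coef.converged:
            assert np.max(np.abs(recon - family_cdf(x, nh_family))) < 1e-3
        else:
            assert np.all(np.isfinite(recon))


class TestOrderStatistics:
    def test_single_observation_is_density(self, nh_family):
        x = np.linspace(0.05, 2, 25)
        assert np.allclose(order_stat_pdf(x, 1, 1, nh_family), family_pdf(x, nh_family))

    def test_normalizes(self, nh_family):
        total, _ = integrate.quad(
            lambda t: float(order_stat_pdf(t, 2, 5, nh_family)), 0, np.inf, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_maximum_matches_simulation(self, nh_family):
        """Sample maxima over many replicates follow n f F^(n-1)."""
        n, reps = 5, 10_000
        draws = family_sample(n * reps, nh_family, seed=23).reshape(reps, n)
        maxima = draws.max(axis=1)

        def max_cdf(t):
            return family_cdf(t, nh_family) ** n

        res = stats.kstest(maxima, max_cdf)
        assert res.pvalue > 0.01

    def test_rank_out_of_range(self, nh_family):
        with pytest.raises(ValueError, match="rank"):
            order_stat_pdf(0.5, 0, 3, nh_family)


class TestShapeDiagnosis:
    def test_reversed_j_density(self):
        p = to_family_params(EGuNHParams(0.3, 2.0, 0.5))
        d = shape_diagnosis(p)
        assert d["pdf_shape"] == "monotone-decreasing"
        assert d["pdf_critical_points"] == []

    def test_unimodal_density(self, nh_family):
        d = shape_diagnosis(nh_family)
        assert d["pdf_shape"] == "unimodal"
        assert len(d["pdf_critical_points"]) == 1

    def test_stable_under_grid_refinement(self, nh_family):
        d1 = shape_diagnosis(nh_family, n_grid=2000)
        d2 = shape_diagnosis(nh_family, n_grid=4000)
        assert d1["hrf_shape"] == d2["hrf_shape"]
        assert d1["pdf_shape"] == d2["pdf_shape"]
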