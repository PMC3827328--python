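"""Censored-normal and censored-bivariate likelihoods against independent oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from clpv.censored import (CensoredSample, OutcomeSpec, SevenParameterModel,
                           bvn_cdf, bvn_rect, fit_censored_normal,
                           fit_seven_parameter_mle, loglik_bivariate,
                           loglik_censored_normal, ordinal_thresholds)
from clpv.simulate import SimulationConfig, simulate_cohort


class TestCensoredSample:
    def test_value_above_ceiling_rejected(self):
        with pytest.raises(ValueError, match="ceiling"):
            CensoredSample(np.array([1.0, 31.0]), np.array([False, False]), 30.0)

    def test_ties_at_ceiling_define_censorship(self):
        s = CensoredSample.from_values([28.0, 30.0, 29.0, 35.0], ceiling=30.0)
        assert s.n_censored == 2
        assert np.all(s.values <= 30.0)


class TestCensoredNormalLoglik:
    def test_no_censoring_equals_plain_normal(self, rng):
        x = rng.normal(1.0, 2.0, 50)
        s = CensoredSample.from_values(x)
        expected = stats.norm.logpdf(x, 0.5, 1.5).sum()
        assert loglik_censored_normal(0.5, 1.5, s) == pytest.approx(expected)

    def test_all_censored_far_below_mu_tends_to_zero(self):
        s = CensoredSample.from_values([30.0] * 20, ceiling=30.0)
        ll = loglik_censored_normal(100.0, 1.0, s)
        assert -1e-9 < ll <= 0.0

    def test_hand_summed_terms(self):
        # n = 5 fixed points, one at the ceiling: term-by-term oracle
        vals = [24.0, 26.0, 28.0, 29.0, 30.0]
        s = CensoredSample.from_values(vals, ceiling=30.0)
        mu, sd = 27.0, 2.5
        expected = sum(stats.norm.logpdf(v, mu, sd) for v in vals[:-1])
        expected += math.log(stats.norm.sf(30.0, mu, sd))
        assert loglik_censored_normal(mu, sd, s) == pytest.approx(expected, abs=1e-12)


class TestCensoredNormalFit:
    def test_uncensored_standard_normal_recovery(self, rng):
        s = CensoredSample.from_values(rng.standard_normal(10000))
        fit = fit_censored_normal(s)
        mu, sd = fit.params
        assert abs(mu) < 0.05 and abs(sd - 1) < 0.05

    def test_a_level_geometry_recovery(self, rng):
        # the decensored applicant pool geometry: N(29.01, 5.89) capped at 30
        x = rng.normal(29.01, 5.89, 50000)
        s = CensoredSample.from_values(x, ceiling=30.0)
        fit = fit_censored_normal(s)
        mu, sd = fit.params
        assert mu == pytest.approx(29.01, abs=0.15)
        assert sd == pytest.approx(5.89, abs=0.15)

    def test_infinite_ceiling_equals_closed_form(self, rng):
        x = rng.normal(2, 3, 200)
        fit = fit_censored_normal(CensoredSample.from_values(x))
        mu, sd = fit.params
        assert mu == pytest.approx(x.mean(), abs=1e-12)
        assert sd == pytest.approx(x.std(ddof=0), abs=1e-12)

    def test_overwhelming_censorship_rejected(self, rng):
        x = np.concatenate([np.full(980, 30.0), rng.normal(25, 2, 20)])
        x = np.minimum(x, 30.0)
        with pytest.raises(ValueError, match="censored"):
            fit_censored_normal(CensoredSample.from_values(x, ceiling=30.0))


class TestOrdinalThresholds:
    def test_median_split(self):
        assert ordinal_thresholds([50, 50]) == pytest.approx([0.0])

    def test_quartiles(self):
        tau = ordinal_thresholds([25, 25, 25, 25])
        assert tau == pytest.approx([-0.6744898, 0.0, 0.6744898], abs=1e-6)

    def test_three_percent_fail_tail(self):
        assert ordinal_thresholds([97, 3]) == pytest.approx([1.8808], abs=1e-4)

    def test_empty_boundary_category_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ordinal_thresholds([0, 10, 5])


class TestBvnCdf:
    def test_against_scipy_multivariate_normal(self):
        pts = [-2.0, -0.7, 0.0, 0.4, 1.3, 2.5]
        for rho in (-0.95, -0.5, 0.0, 0.3, 0.8, 0.99):
            cov = [[1, rho], [rho, 1]]
            mvn = stats.multivariate_normal(mean=[0, 0], cov=cov)
            for h in pts:
                for k in pts:
                    assert bvn_cdf(h, k, rho) == pytest.approx(
                        float(mvn.cdf([h, k])), abs=1e-7)

    def test_rectangle_marginal_consistency(self):
        # integrating y out of the rectangle returns the x marginal
        p = bvn_rect(-0.5, 1.2, -np.inf, np.inf, 0.6)
        assert p == pytest.approx(stats.norm.cdf(1.2) - stats.norm.cdf(-0.5),
                                  abs=1e-12)


def _quad_loglik(m, x, y, spec, ceiling):
    """Numeric double-integration oracle for the censored bivariate loglik."""
    def density(xv, yv):
        cov = np.array([[m.sigma_i ** 2, m.r_i * m.sigma_i * m.sigma_y],
                        [m.r_i * m.sigma_i * m.sigma_y, m.sigma_y ** 2]])
        return stats.multivariate_normal([m.mu_i, m.mu_y], cov).pdf([xv, yv])

    total = 0.0
    for xi, yi in zip(x, y):
        if spec.is_latent:
            tau = np.concatenate(([-np.inf], spec.thresholds, [np.inf]))
            lo, hi = tau[int(yi)], tau[int(yi) + 1]
            if xi >= ceiling:
                p, _ = integrate.dblquad(
                    lambda yv, xv: stats.norm.pdf(xv, m.mu_i, m.sigma_i)
                    * stats.norm.pdf(yv, m.r_i * xv_std(xv, m), math.sqrt(1 - m.r_i ** 2)),
                    ceiling, m.mu_i + 10 * m.sigma_i,
                    lambda _: max(lo, -12), lambda _: min(hi, 12),
                    epsabs=1e-12)
            else:
                p, _ = integrate.quad(
                    lambda yv: stats.norm.pdf(yv, m.r_i * xv_std(xi, m),
                                              math.sqrt(1 - m.r_i ** 2)),
                    max(lo, -12), min(hi, 12), epsabs=1e-13)
                p *= stats.norm.pdf(xi, m.mu_i, m.sigma_i)
        else:
            if xi >= ceiling:
                p, _ = integrate.quad(lambda xv: density(xv, yi), ceiling,
                                      m.mu_i + 10 * m.sigma_i, epsabs=1e-13)
            else:
                p = density(xi, yi)
        total += math.log(p)
    return total


def xv_std(xv, m):
    return (xv - m.mu_i) / m.sigma_i


class TestBivariateLoglik:
    def test_independence_factorisation(self, rng):
        x = rng.normal(1, 2, 30)
        y = rng.normal(-1, 0.5, 30)
        m = SevenParameterModel(0, 1, 1.2, 1.8, -0.8, 0.6, 0.0)
        ll = loglik_bivariate(m, x, y)
        expected = (stats.norm.logpdf(x, 1.2, 1.8).sum()
                    + stats.norm.logpdf(y, -0.8, 0.6).sum())
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_continuous_against_quadrature(self):
        x = np.array([0.2, -0.5, 1.5, 1.5])   # ceiling 1.5: one censored
        y = np.array([0.1, -0.2, 0.9, 0.4])
        m = SevenParameterModel(0, 1, 0.3, 0.9, 0.1, 0.8, 0.45)
        spec = OutcomeSpec()
        ours = loglik_bivariate(m, x, y, spec, ceiling=1.5)
        oracle = _quad_loglik(m, x, y, spec, 1.5)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_ordinal_against_quadrature(self):
        spec = OutcomeSpec(kind="ordinal", categories=("f", "r", "p", "h"),
                           thresholds=np.array([-1.5, -0.5, 1.0]))
        x = np.array([0.0, 0.8, 1.2, 1.2])
        y = np.array([1, 2, 3, 0], dtype=float)
        m = SevenParameterModel(0, 1, 0.4, 0.7, 0.0, 1.0, -0.35)
        ours = loglik_bivariate(m, x, y, spec, ceiling=1.2)
        oracle = _quad_loglik(m, x, y, spec, 1.2)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_out_of_range_correlation_is_minus_inf(self):
        m = SevenParameterModel(0, 1, 0, 1, 0, 1, 1.0)
        assert loglik_bivariate(m, [0.0], [0.0]) == -math.inf

    def test_binary_mle_matches_tetrachoric_oracle(self, rng):
        # simulate latent bivariate normal, dichotomise both margins
        rho = 0.5
        n = 6000
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + math.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        x = z1
        yb = (z2 > 0.3).astype(float)
        spec = OutcomeSpec(kind="binary", categories=("0", "1"),
                           thresholds=ordinal_thresholds(
                               np.bincount(yb.astype(int))))
        apps = CensoredSample.from_values(rng.standard_normal(2000))
        fit = fit_seven_parameter_mle(apps, x, yb, spec=spec)
        # independent tetrachoric estimate from the dichotomised 2x2 table
        xb = (x > 0).astype(int)
        p11 = np.mean((xb == 1) & (yb == 1))
        tau_x = stats.norm.ppf(1 - xb.mean())
        tau_y = stats.norm.ppf(1 - yb.mean())
        mvncdf = stats.multivariate_normal([0, 0])

        def cell(r):
            c = stats.multivariate_normal([0, 0], [[1, r], [r, 1]])
            return c.cdf([-tau_x, -tau_y]) - p11
        tetra = optimize.brentq(cell, -0.99, 0.99)
        # the polyserial-type MLE uses the continuous x, so agreement is
        # statistical, not exact
        assert fit.params.r_i == pytest.approx(tetra, abs=0.05)


class TestSevenParameterMle:
    def test_recovers_generative_parameters(self, default_cohort):
        c = default_cohort
        fit = fit_seven_parameter_mle(c.applicants, c.entrants_x, c.entrants_y,
                                      ceiling=c.ceiling)
        m, truth = fit.params, c.truth["model"]
        # entrant moments are pseudo-true under selection; applicants exact
        assert m.mu_a == pytest.approx(truth.mu_a, abs=0.05)
        assert m.sigma_a == pytest.approx(truth.sigma_a, abs=0.05)
        assert m.r_i == pytest.approx(truth.r_i, abs=0.05)
        assert m.mu_y == pytest.approx(truth.mu_y, abs=0.05)

    def test_entrants_equal_applicants_uncensored(self, rng):
        x = rng.normal(0, 1, 4000)
        y = 0.4 * x + rng.normal(0, 1, 4000)
        apps = CensoredSample.from_values(x)
        fit = fit_seven_parameter_mle(apps, x, y)
        m = fit.params
        assert m.mu_a == pytest.approx(m.mu_i, abs=0.02)
        assert m.sigma_a == pytest.approx(m.sigma_i, abs=0.02)

    def test_reduces_to_sample_moments_without_censoring(self, rng):
        x = rng.normal(1, 2, 500)
        y = rng.normal(-2, 1.5, 500) + 0.5 * x
        apps = CensoredSample.from_values(rng.normal(1, 2.4, 800))
        fit = fit_seven_parameter_mle(apps, x, y)
        m = fit.params
        assert m.mu_i == pytest.approx(x.mean(), abs=1e-5)
        assert m.sigma_i == pytest.approx(x.std(ddof=0), rel=1e-4)
        assert m.mu_y == pytest.approx(y.mean(), abs=1e-5)
        assert m.sigma_y == pytest.approx(y.std(ddof=0), rel=1e-4)
        assert m.r_i == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-4)

    def test_affine_rescaling_invariance(self, rng):
        x = rng.normal(0, 1, 200)
        y = 0.5 * x + rng.normal(0, 1, 200)
        m = SevenParameterModel(0, 1, 0.1, 0.9, 0.0, 1.1, 0.5)
        base = loglik_bivariate(m, x, y)
        a, b = 3.0, 2.0
        m2 = SevenParameterModel(0, 1, 0.1, 0.9, a + b * 0.0, b * 1.1, 0.5)
        shifted = loglik_bivariate(m2, x, a + b * y)
        # densities pick up the |b| Jacobian per observation
        assert shifted == pytest.approx(base - x.size * math.log(b), abs=1e-8)

    def test_raising_ceiling_leaves_uncensored_terms_alone(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        m = SevenParameterModel(0, 1, 0, 1, 0, 1, 0.3)
        ll_hi = loglik_bivariate(m, x, y, ceiling=np.max(x) + 1)
        ll_inf = loglik_bivariate(m, x, y, ceiling=math.inf)
        assert ll_hi == pytest.approx(ll_inf, abs=1e-12)

    def test_heavy_censoring_still_identifies_r(self):
        cfg = SimulationConfig(n_applicants=20000, ceiling_quantile=0.8,
                               selection_fraction=0.3, seed=9)
        c = simulate_cohort(cfg)
        frac_cens = np.mean(c.entrants_x >= c.ceiling)
        assert frac_cens > 0.45    # heavy censorship in entrants
        fit = fit_seven_parameter_mle(c.applicants, c.entrants_x, c.entrants_y,
                                      ceiling=c.ceiling)
        assert fit.params.r_i == pytest.approx(c.truth["model"].r_i, abs=0.05)
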