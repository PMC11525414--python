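"""2-AFC psychometric links: closed forms, Monte-Carlo oracles, fitting."""

import numpy as np
import pytest
from scipy.stats import norm

from analogue_report import (InsufficientDataError, bvn_cdf, draw_mixture_errors,
                             fit_afc_async, fit_afc_sync, pcorr_async,
                             pcorr_sync, psi_init, psi_select, psi_update, wrap)


def sync_product_form(d, sigma):
    """Independent closed-form oracle: the (V−U, V+U) factorization."""
    a = d / (sigma * np.sqrt(6.0))
    b = d / (sigma * np.sqrt(2.0))
    return norm.cdf(-a) * norm.cdf(-b) + norm.cdf(a) * norm.cdf(b)


class TestPcorrAsync:
    def test_forced_guess_at_zero(self):
        for kappa, alpha in [(1.0, 0.2), (8.0, 0.9), (100.0, 1.0)]:
            assert pcorr_async(0.0, kappa, alpha) == pytest.approx(0.5)

    def test_opposite_colours_negligible_noise(self):
        assert pcorr_async(np.pi, 500.0, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_decision_rule_oracle(self, rng):
        n = 10**6
        for d, kappa, alpha in [(np.pi / 2, 4.0, 0.9), (0.3, 8.0, 0.95),
                                (1.5, 2.0, 0.7)]:
            y = draw_mixture_errors(kappa, alpha, n, rng)
            correct = np.abs(y) < np.abs(wrap(y - d))
            ties = np.abs(y) == np.abs(wrap(y - d))
            p_hat = float(np.mean(correct) + 0.5 * np.mean(ties))
            se = np.sqrt(p_hat * (1 - p_hat) / n)
            assert pcorr_async(d, kappa, alpha) == pytest.approx(
                p_hat, abs=3 * se)

    def test_mixture_linearity(self):
        d = np.linspace(0, np.pi, 25)
        for kappa in [0.5, 4.0, 50.0]:
            for alpha in [0.0, 0.3, 0.8]:
                lhs = pcorr_async(d, kappa, alpha)
                rhs = alpha * pcorr_async(d, kappa, 1.0) + (1 - alpha) / 2
                np.testing.assert_allclose(lhs, rhs, atol=1e-14)

    def test_monotone_and_bounded(self):
        d = np.linspace(0, np.pi, 500)
        for kappa, alpha in [(0.5, 0.6), (8.0, 0.95), (200.0, 1.0)]:
            p = pcorr_async(d, kappa, alpha)
            assert np.all(np.diff(p) >= -1e-12)
            assert np.all(p >= 0.5 - 1e-12) and np.all(p <= 1 + 1e-12)

    def test_high_concentration_tends_to_one(self):
        d = np.linspace(0.05, np.pi, 50)
        assert np.all(pcorr_async(d, 1e4, 1.0) > 0.99)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            pcorr_async(3.5, 4.0, 0.9)


class TestPcorrSync:
    def test_forced_guess_at_zero(self):
        assert pcorr_sync(0.0, 0.2) == pytest.approx(0.5)

    def test_vanishing_noise_limit(self):
        assert pcorr_sync(0.8, 0.01) == pytest.approx(1.0, abs=1e-6)

    def test_product_form_grid(self):
        # bivariate-CDF implementation vs the factorized closed form
        d = np.linspace(0.0, np.pi, 20)
        sigmas = np.linspace(0.02, 1.0, 20)
        for s in sigmas:
            np.testing.assert_allclose(pcorr_sync(d, s),
                                       sync_product_form(d, s), atol=1e-10)

    def test_monte_carlo_decision_rule_oracle(self, rng):
        n = 10**6
        for d, sigma in [(0.5, 0.2), (0.2, 0.15), (1.0, 0.3)]:
            eps = rng.normal(0.0, sigma, (3, n))  # t, p, f
            d_probe = np.abs(wrap(eps[1] - eps[0]))
            d_foil = np.abs(wrap(d + eps[2] - eps[0]))
            p_hat = float(np.mean(d_probe < d_foil))
            se = np.sqrt(p_hat * (1 - p_hat) / n)
            assert pcorr_sync(d, sigma) == pytest.approx(p_hat, abs=3 * se)

    def test_monotone_in_d_and_sigma(self):
        d = np.linspace(0, np.pi, 300)
        p = pcorr_sync(d, 0.25)
        assert np.all(np.diff(p) >= -1e-12)
        for dd in [0.3, 1.0]:
            vals = [pcorr_sync(dd, s) for s in np.linspace(0.05, 1.0, 40)]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pcorr_sync(0.5, -0.1)
        with pytest.raises(ValueError):
            pcorr_sync(4.0, 0.2)


class TestBvnCdf:
    def test_zero_correlation_factorizes(self, rng):
        h = rng.normal(0, 1.5, 50)
        k = rng.normal(0, 1.5, 50)
        np.testing.assert_allclose(bvn_cdf(h, k, 0.0),
                                   norm.cdf(h) * norm.cdf(k), atol=1e-12)

    def test_correlated_against_quadrature(self):
        from scipy import integrate

        for h, k, rho in [(0.3, -0.5, 0.6), (-1.0, 0.2, -0.4), (0.0, 0.7, 0.3)]:
            def inner(x):
                # P(Y <= k | X = x) integrated against the X density
                return norm.pdf(x) * norm.cdf((k - rho * x) / np.sqrt(1 - rho**2))
            val, _ = integrate.quad(inner, -9, h, epsabs=1e-12, limit=300)
            assert bvn_cdf(h, k, rho) == pytest.approx(val, abs=1e-9)


def _psi_driven_trials(kappa, alpha, n_trials, rng):
    state = psi_init()
    d_list, c_list = [], []
    for _ in range(n_trials):
        d = psi_select(state)
        c = bool(rng.random() < pcorr_async(d, kappa, alpha))
        state = psi_update(state, d, c)
        d_list.append(d)
        c_list.append(c)
    return np.array(d_list), np.array(c_list)


class TestFitAfcAsync:
    def test_recovery_over_psi_observers(self, rng):
        # 80 adaptively placed trials per observer, 50 replicate observers
        kappas = []
        for _ in range(50):
            d, c = _psi_driven_trials(8.0, 0.95, 80, rng)
            kappas.append(fit_afc_async((d, c)).kappa_t)
        assert np.median(kappas) == pytest.approx(8.0, rel=0.25)

    def test_guess_regime(self, rng):
        d = rng.uniform(0.05, np.pi, 2000)
        c = rng.random(2000) < 0.5
        fit = fit_afc_async((d, c))
        assert fit.alpha <= 0.1

    def test_all_correct_hits_bounds_with_flag(self, rng):
        d = rng.uniform(0.5, np.pi, 100)
        fit = fit_afc_async((d, np.ones(100, dtype=bool)))
        assert fit.at_bound

    def test_degenerate_design_rejected(self):
        d = np.full(60, 1.0)
        c = np.ones(60, dtype=bool)
        with pytest.raises(InsufficientDataError):
            fit_afc_async((d, c))
        with pytest.raises(InsufficientDataError):
            fit_afc_async((np.linspace(0.1, 3, 10), np.ones(10, dtype=bool)))


class TestFitAfcSync:
    def test_recovery_over_replicates(self, rng):
        sigma = 0.15
        estimates = []
        for _ in range(50):
            d = rng.uniform(0.02, np.pi, 2000)
            c = rng.random(2000) < pcorr_sync(d, sigma)
            estimates.append(fit_afc_sync((d, c)).sigma_t)
        assert np.median(estimates) == pytest.approx(sigma, rel=0.10)

    def test_all_correct_lower_bound_flagged(self, rng):
        d = rng.uniform(0.5, np.pi, 100)
        fit = fit_afc_sync((d, np.ones(100, dtype=bool)))
        assert fit.at_bound
        assert fit.sigma_t <= 1e-3

    def test_kappa_equivalent_finite(self, rng):
        from analogue_report import sigma_to_kappa

        d = rng.uniform(0.02, np.pi, 500)
        c = rng.random(500) < pcorr_sync(d, 0.2)
        fit = fit_afc_sync((d, c))
        kappa = sigma_to_kappa(fit.sigma_t)
        assert np.isfinite(kappa) and kappa > 0
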