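"""Psychometric linking models for the 2-AFC colour discrimination task.

Both models predict the probability of choosing the probe (p = t) over a
foil at circular distance d = |f ⊖ t|, from the same internal quantities
the analogue-report models estimate, so parameters are directly comparable
across response methods.

Asynchronous (memory) condition — the observer holds a noisy internal
estimate y of the target, distributed as the contamination mixture, and
picks whichever of probe and foil lies closer to y on the circle:

    Pr_corr(d) = α [Φ_VM(d/2; 0, κ_t) − Φ_VM(d/2 − π; 0, κ_t)] + (1 − α)/2.

Synchronous (perception) condition — target, probe, foil and wheel colours
are all visible and carry small, equal, independent Gaussian noise; lapses
are assumed absent. The nearest-to-target rule Pr(|p̂ ⊖ t̂| < |f̂ ⊖ t̂|)
reduces to a sum of two bivariate-normal orthant probabilities with mean
[d/√2, d/√2] and covariance diag(3σ_t², σ_t²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .circular import vm_cdf
from .errors import ConvergenceError, InsufficientDataError
from .mixture import KAPPA_MAX, KAPPA_MIN, _LOGIT_BOUND

__all__ = [
    "AFCAsyncParams",
    "AFCSyncParams",
    "pcorr_async",
    "pcorr_sync",
    "fit_afc_async",
    "fit_afc_sync",
    "bvn_cdf",
]

SIGMA_MIN = 1e-4
SIGMA_MAX = np.pi


@dataclass
class AFCAsyncParams:
    """Contamination-model parameters recovered from asynchronous 2-AFC choices."""

    kappa_t: float
    alpha: float
    loglik: float = np.nan
    n_trials: int = 0
    at_bound: bool = False


@dataclass
class AFCSyncParams:
    """Representational SD recovered from synchronous 2-AFC choices."""

    sigma_t: float
    loglik: float = np.nan
    n_trials: int = 0
    at_bound: bool = False

    @property
    def mean_vector(self):
        raise AttributeError("mean vector depends on foil distance; use moments(d)")

    def moments(self, d: float):
        """Mean vector and covariance of the decision variables at foil distance d."""
        mu = np.array([d / np.sqrt(2.0), d / np.sqrt(2.0)])
        cov = np.diag([3.0 * self.sigma_t**2, self.sigma_t**2])
        return mu, cov


def _phi(x):
    return special.ndtr(x)


def bvn_cdf(h, k, rho=0.0):
    """Standard bivariate normal CDF Pr(X ≤ h, Y ≤ k) with correlation ρ.

    Owen's (1956) closed form via the T function,

        Φ₂(h, k; ρ) = [Φ(h) + Φ(k)]/2 − T(h, a_h) − T(k, a_k) − c,

    exact to machine precision — no quadrature or quasi-Monte-Carlo error.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(rho)
    if not -1.0 < rho < 1.0:
        raise ValueError("bvn_cdf: rho must lie in (-1, 1)")
    denom = np.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_h = np.where(h != 0.0, (k - rho * h) / (h * denom), np.inf * np.sign(k))
        a_k = np.where(k != 0.0, (h - rho * k) / (k * denom), np.inf * np.sign(h))
    # T(0, a) = arctan(a)/2pi; scipy's owens_t handles infinite a
    t_h = np.where(h != 0.0, special.owens_t(h, a_h),
                   np.arctan(a_h) / (2.0 * np.pi))
    t_k = np.where(k != 0.0, special.owens_t(k, a_k),
                   np.arctan(a_k) / (2.0 * np.pi))
    c = np.where((h * k < 0.0) | ((h * k == 0.0) & (h + k < 0.0)), 0.5, 0.0)
    both_zero = (h == 0.0) & (k == 0.0)
    out = 0.5 * (_phi(h) + _phi(k)) - t_h - t_k - c
    out = np.where(both_zero, 0.25 + np.arcsin(rho) / (2.0 * np.pi), out)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def pcorr_async(d, kappa_t, alpha):
    """Probability correct vs foil distance under the contamination link.

    Nondecreasing in d; 1/2 at d = 0 (foil equals probe, forced guess);
    bounded below by (1 − α)/2 + α/2 = chance when discrimination carries
    no information.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < -1e-12) or np.any(d > np.pi + 1e-12):
        raise ValueError("pcorr_async: d must lie in [0, pi]")
    d = np.clip(d, 0.0, np.pi)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("pcorr_async: alpha must lie in [0, 1]")
    p = alpha * (vm_cdf(d / 2.0, 0.0, kappa_t)
                 - vm_cdf(d / 2.0 - np.pi, 0.0, kappa_t)) + (1.0 - alpha) / 2.0
    return p if np.ndim(p) else float(p)


def pcorr_sync(d, sigma_t):
    """Probability correct under the synchronous bivariate-normal model.

    Evaluates Φ²_{μ,Σ}(0) + Φ²_{−μ,Σ}(0) with μ = [d/√2, d/√2] and
    Σ = diag(3σ_t², σ_t²). Increasing in d, decreasing in σ_t; 1/2 at
    d = 0. Noise is treated linearly (no wrapping), as the small-noise
    assumption of the model dictates; accuracy degrades for σ_t ≳ 0.5 rad.
    """
    sigma_t = float(sigma_t)
    if sigma_t <= 0:
        raise ValueError("pcorr_sync: sigma_t must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < -1e-12) or np.any(d > np.pi + 1e-12):
        raise ValueError("pcorr_sync: d must lie in [0, pi]")
    d = np.clip(d, 0.0, np.pi)
    z1 = -d / (sigma_t * np.sqrt(6.0))  # standardized against 3 sigma^2
    z2 = -d / (sigma_t * np.sqrt(2.0))
    p = bvn_cdf(z1, z2, 0.0) + bvn_cdf(-z1, -z2, 0.0)
    p = np.clip(p, 0.5, 1.0)
    return p if np.ndim(p) else float(p)


def _design_arrays(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        d = np.abs(trials["delta_rad"].to_numpy(dtype=float))
        correct = trials["correct"].to_numpy().astype(bool)
    else:
        d, correct = trials
        d = np.abs(np.asarray(d, dtype=float))
        correct = np.asarray(correct).astype(bool)
    return d, correct


def _check_design(d: np.ndarray, min_trials: int, min_levels: int) -> None:
    if d.size < min_trials:
        raise InsufficientDataError(
            f"2-AFC fit: {d.size} trials < floor of {min_trials}")
    if np.unique(np.round(d, 6)).size < min_levels:
        raise InsufficientDataError(
            f"2-AFC fit: fewer than {min_levels} distinct |delta| levels")


def _binom_nll(p: np.ndarray, correct: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(np.where(correct, np.log(p), np.log1p(-p))))


def fit_afc_async(trials, min_trials: int = 20, min_levels: int = 5) -> AFCAsyncParams:
    """Binomial MLE of (κ_t, α) under :func:`pcorr_async`.

    ``trials`` is a trial table (``delta_rad``, ``correct``) or a
    ``(d, correct)`` pair of arrays. Same restart policy as the analogue
    contamination fit. All-correct data drive both parameters to their
    upper bounds; the returned ``at_bound`` flag marks such separation.
    """
    d, correct = _design_arrays(trials)
    _check_design(d, min_trials, min_levels)

    def nll(z):
        kappa = np.exp(z[0])
        alpha = special.expit(z[1])
        return _binom_nll(pcorr_async(d, kappa, alpha), correct)

    starts = [(4.0, 0.9), (1.0, 0.5), (16.0, 0.95), (64.0, 0.95), (0.5, 0.7),
              (8.0, 0.99)]
    bounds = [(np.log(KAPPA_MIN), np.log(KAPPA_MAX)),
              (-_LOGIT_BOUND, _LOGIT_BOUND)]
    best, diagnostics = None, []
    for k0, a0 in starts:
        z0 = np.array([np.log(k0), special.logit(a0)])
        res = optimize.minimize(nll, z0, method="L-BFGS-B", bounds=bounds)
        diagnostics.append({"start": (k0, a0), "success": bool(res.success),
                            "fun": float(res.fun)})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError("fit_afc_async: no restart converged",
                               {"restarts": diagnostics})
    kappa = float(np.exp(best.x[0]))
    alpha = float(special.expit(best.x[1]))
    at_bound = (abs(best.x[0] - np.log(KAPPA_MAX)) < 1e-6
                or abs(best.x[1] - _LOGIT_BOUND) < 1e-6)
    return AFCAsyncParams(kappa_t=kappa, alpha=alpha, loglik=-float(best.fun),
                          n_trials=int(d.size), at_bound=at_bound)


def fit_afc_sync(trials, min_trials: int = 20, min_levels: int = 5) -> AFCSyncParams:
    """Binomial MLE of σ_t under :func:`pcorr_sync`.

    One-dimensional search over log σ_t on [1e-4, π], seeded from a coarse
    grid. All-correct data drive σ_t to the lower bound (flagged).
    """
    d, correct = _design_arrays(trials)
    _check_design(d, min_trials, min_levels)

    def nll(logsig):
        return _binom_nll(pcorr_sync(d, float(np.exp(logsig))), correct)

    if correct.all():
        # perfect separation: likelihood plateaus as sigma -> 0
        sigma = SIGMA_MIN
        return AFCSyncParams(sigma_t=sigma, loglik=-nll(np.log(sigma)),
                             n_trials=int(d.size), at_bound=True)

    grid = np.log(np.geomspace(SIGMA_MIN * 2, SIGMA_MAX / 2, 25))
    vals = [nll(g) for g in grid]
    z0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        nll, bounds=(np.log(SIGMA_MIN), np.log(SIGMA_MAX)), method="bounded",
        options={"xatol": 1e-10})
    if not res.success or res.fun > min(vals) + 1e-6:
        # bounded Brent missed the grid optimum's basin: polish from grid
        try:
            res2 = optimize.minimize_scalar(
                nll, bracket=(z0 - 0.5, z0 + 0.5), method="brent")
            if res2.fun < res.fun:
                res = res2
        except Exception:
            pass
    if not np.isfinite(res.fun):
        raise ConvergenceError("fit_afc_sync: optimizer failed", {"res": str(res)})
    sigma = float(np.clip(np.exp(res.x), SIGMA_MIN, SIGMA_MAX))
    at_bound = sigma <= SIGMA_MIN * (1 + 1e-6) or sigma >= SIGMA_MAX * (1 - 1e-6)
    return AFCSyncParams(sigma_t=sigma, loglik=-float(res.fun),
                         n_trials=int(d.size), at_bound=at_bound)
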