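"""Circular arithmetic and von Mises utilities.

All angles are radians on the canonical interval (−π, π]. Degrees appear
only at I/O boundaries (human-readable summaries, motor-noise projections).

The σ↔κ conversion maps a Gaussian/wrapped-normal standard deviation to the
von Mises concentration with the same mean resultant length,

    I₁(κ)/I₀(κ) = exp(−σ²/2),

which is the standard wrapped-normal equivalence. It is deliberately
isolated here so an alternative convention (e.g. κ = 1/σ²) could be swapped
in one place.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, special

__all__ = [
    "wrap",
    "circ_diff",
    "cosine_dissimilarity",
    "circular_sd",
    "vm_pdf",
    "vm_cdf",
    "sigma_to_kappa",
    "kappa_to_sigma",
]

TWO_PI = 2.0 * np.pi


def wrap(x):
    """Wrap angle(s) to the canonical interval (−π, π].

    Parameters
    ----------
    x : array_like
        Angle(s) in radians. Must be finite.

    Returns
    -------
    ndarray or float
        ``x`` reduced modulo 2π into (−π, π].
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap: input must be finite")
    # map to [-pi, pi) then move the open edge: -pi -> pi
    w = np.mod(x + np.pi, TWO_PI) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return w if w.ndim else float(w)


def circ_diff(a, b):
    """Signed angular difference a ⊖ b, wrapped to (−π, π]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("circ_diff: inputs must be finite")
    return wrap(a - b)


def cosine_dissimilarity(errors) -> float:
    """Mean of 1 − cos(error) over trials; a dispersion statistic in [0, 2].

    Zero for perfect reproduction, 1 in expectation for uniformly random
    errors, 2 for consistently antipodal responses.
    """
    errors = np.atleast_1d(np.asarray(errors, dtype=float))
    if errors.size == 0:
        raise ValueError("cosine_dissimilarity: empty error list")
    if not np.all(np.isfinite(errors)):
        raise ValueError("cosine_dissimilarity: errors must be finite")
    return float(np.mean(1.0 - np.cos(errors)))


def circular_sd(angles) -> float:
    """Circular standard deviation √(−2 ln R̄) of a sample of angles."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("circular_sd: empty sample")
    rbar = float(np.hypot(np.mean(np.sin(angles)), np.mean(np.cos(angles))))
    if rbar <= 0.0:
        return np.inf
    rbar = min(rbar, 1.0)
    return float(np.sqrt(max(-2.0 * np.log(rbar), 0.0)))


def vm_pdf(theta, mu=0.0, kappa=1.0):
    """Von Mises density φ_VM(θ; μ, κ); κ = 0 is the uniform circle."""
    theta = np.asarray(theta, dtype=float)
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("vm_pdf: kappa must be >= 0")
    if kappa == 0.0:
        out = np.full_like(theta, 1.0 / TWO_PI, dtype=float)
        return out if out.ndim else float(out)
    # exponentially scaled Bessel keeps large kappa finite
    out = np.exp(kappa * (np.cos(theta - mu) - 1.0)) / (TWO_PI * special.i0e(kappa))
    return out if out.ndim else float(out)


def vm_cdf(theta, mu=0.0, kappa=1.0):
    """Cumulative von Mises Φ_VM(θ; μ, κ) = ∫_{−π}^{θ} φ_VM(x; μ, κ) dx.

    Defined for θ ∈ [−π, π]; Φ(−π) = 0 and Φ(π) = 1. κ = 0 gives the
    uniform CDF (θ + π)/(2π).
    """
    theta = np.asarray(theta, dtype=float)
    kappa = float(kappa)
    if kappa < 0:
        raise ValueError("vm_cdf: kappa must be >= 0")
    if np.any(theta < -np.pi - 1e-12) or np.any(theta > np.pi + 1e-12):
        raise ValueError("vm_cdf: theta must lie in [-pi, pi]")
    theta = np.clip(theta, -np.pi, np.pi)
    if kappa == 0.0:
        out = (theta + np.pi) / TWO_PI
        return out if out.ndim else float(out)
    # Fourier series of the centred cdf:
    #   C(x) = x/(2pi) + (1/pi) sum_j [I_j(k)/I_0(k)] sin(jx)/j,
    # with exact coefficients and truncation error < 1e-14; the integral
    # from -pi is C(theta - mu) - C(-pi - mu).
    ratios = _fourier_ratios(kappa)
    j = np.arange(1, ratios.size + 1)

    def centred(x):
        x = np.asarray(x, dtype=float)
        series = np.sin(np.multiply.outer(x, j)) @ (ratios / j)
        return x / TWO_PI + series / np.pi

    out = centred(theta - mu) - centred(-np.pi - mu)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


@lru_cache(maxsize=256)
def _fourier_ratios(kappa: float) -> np.ndarray:
    """I_j(κ)/I_0(κ) for j = 1..J, with J adapted so the tail is < 1e-15."""
    n = 64
    while True:
        j = np.arange(1, n + 1)
        ratios = special.ive(j, kappa) / special.i0e(kappa)
        if ratios[-1] < 1e-16 or n >= 1 << 17:
            below = np.nonzero(ratios < 1e-16)[0]
            keep = int(below[0]) + 1 if below.size else ratios.size
            ratios = np.ascontiguousarray(ratios[:keep])
            ratios.setflags(write=False)
            return ratios
        n *= 2


def _log_mean_resultant(kappa: float) -> float:
    # log(I1(k)/I0(k)) via exponentially scaled Bessels, stable for all k
    return float(np.log(special.i1e(kappa)) - np.log(special.i0e(kappa)))


def sigma_to_kappa(sigma: float) -> float:
    """Concentration κ whose mean resultant length matches SD ``sigma``.

    Solves I₁(κ)/I₀(κ) = exp(−σ²/2). Strictly decreasing in σ; κ ≈ 1/σ²
    as σ → 0.
    """
    sigma = float(sigma)
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("sigma_to_kappa: sigma must be positive and finite")
    target = -0.5 * sigma * sigma  # log R
    f = lambda k: _log_mean_resultant(k) - target
    lo, hi = 1e-12, max(4.0 / (sigma * sigma), 10.0)
    while f(hi) < 0:  # R(hi) still below target: enlarge bracket
        hi *= 10.0
        if hi > 1e16:
            break
    return float(optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))


def kappa_to_sigma(kappa: float) -> float:
    """Inverse of :func:`sigma_to_kappa`: σ = √(−2 ln[I₁(κ)/I₀(κ)])."""
    kappa = float(kappa)
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError("kappa_to_sigma: kappa must be positive and finite")
    return float(np.sqrt(-2.0 * _log_mean_resultant(kappa)))
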