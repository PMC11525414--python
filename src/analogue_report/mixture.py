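"""Contamination-mixture and synchronous-Gaussian models for analogue report.

The contamination model describes continuous-report errors as a mixture of
target-related responses (von Mises centred on the target, concentration
κ_t) and uniformly distributed contaminant responses:

    p(y) = α φ_VM(y; t, κ_t) + (1 − α) / 2π,

with α the proportion of target-related responses. It is a descriptive
decomposition; no psychological process is attached to either component.

For synchronous report (the stimulus remains visible while responding) the
response error is treated as Gaussian with SD σ_y collecting equal,
independent noise in the target representation and in the colours on the
response wheel, so σ_y = √(σ_w² + σ_t²) = √2 σ_t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .circular import circ_diff, circular_sd, vm_pdf, wrap
from .errors import ConvergenceError, InsufficientDataError

__all__ = [
    "ContaminationParams",
    "SyncGaussianParams",
    "contamination_pdf",
    "fit_contamination",
    "fit_sync_gaussian",
]

KAPPA_MIN = 1e-4
KAPPA_MAX = 1e4
_LOGIT_BOUND = 15.0  # |logit alpha| cap: alpha within ~3e-7 of {0, 1}


@dataclass
class ContaminationParams:
    """MLE of the contamination mixture plus fit metadata."""

    kappa_t: float
    alpha: float
    loglik: float = np.nan
    n_trials: int = 0
    converged: bool = True
    at_bound: bool = False

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.kappa_t < 0:
            raise ValueError("kappa_t must be >= 0")


@dataclass
class SyncGaussianParams:
    """Synchronous-report Gaussian model: observed σ_y and per-representation σ_t."""

    sigma_y: float
    sigma_t: float = field(default=None)  # type: ignore[assignment]
    n_trials: int = 0

    def __post_init__(self):
        if self.sigma_y < 0:
            raise ValueError("sigma_y must be >= 0")
        if self.sigma_t is None:
            self.sigma_t = self.sigma_y / np.sqrt(2.0)


def contamination_pdf(y, t, kappa_t, alpha):
    """Mixture density α φ_VM(y; t, κ_t) + (1 − α)/2π.

    Strictly positive for α < 1 or finite κ; integrates to 1 over any
    2π interval.
    """
    alpha = float(alpha)
    kappa_t = float(kappa_t)
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("contamination_pdf: alpha must lie in [0, 1]")
    if kappa_t < 0:
        raise ValueError("contamination_pdf: kappa_t must be >= 0")
    e = circ_diff(y, t)
    return alpha * vm_pdf(e, 0.0, kappa_t) + (1.0 - alpha) / (2.0 * np.pi)


def response_errors(trials: pd.DataFrame) -> np.ndarray:
    """Wrapped errors y ⊖ t from a trial table with target_rad/response_rad."""
    return np.asarray(circ_diff(trials["response_rad"].to_numpy(),
                                trials["target_rad"].to_numpy()))


def _as_errors(trials) -> np.ndarray:
    if isinstance(trials, pd.DataFrame):
        return response_errors(trials)
    return np.asarray(wrap(np.asarray(trials, dtype=float)))


def _nll(z: np.ndarray, errors: np.ndarray) -> float:
    logk, la = z
    kappa = np.exp(logk)
    alpha = special.expit(la)
    dens = alpha * vm_pdf(errors, 0.0, kappa) + (1.0 - alpha) / (2.0 * np.pi)
    return -float(np.sum(np.log(dens)))


def _moment_start(errors: np.ndarray) -> tuple[float, float]:
    # alpha from the mass within +/- pi/2 (uniform puts 1/2 there);
    # kappa from the resultant length corrected for that alpha
    p_half = float(np.mean(np.abs(errors) <= np.pi / 2))
    alpha0 = np.clip(2.0 * p_half - 1.0, 0.05, 0.99)
    rbar = float(np.hypot(np.mean(np.sin(errors)), np.mean(np.cos(errors))))
    r_t = np.clip(rbar / alpha0, 1e-3, 1.0 - 1e-9)
    from .circular import sigma_to_kappa

    kappa0 = np.clip(sigma_to_kappa(np.sqrt(-2.0 * np.log(r_t))), KAPPA_MIN, KAPPA_MAX)
    return float(kappa0), float(alpha0)


_START_GRID = [(1.0, 0.5), (4.0, 0.9), (16.0, 0.9), (64.0, 0.95), (0.25, 0.3)]


def fit_contamination(trials, min_trials: int = 10) -> ContaminationParams:
    """Maximum-likelihood fit of (κ_t, α) to wrapped response errors.

    Accepts a trial table (``target_rad``/``response_rad`` columns) or a
    plain array of errors. Optimizes over (log κ, logit α) with κ bounded
    in [1e-4, 1e4], from a deterministic start grid plus a
    method-of-moments start; mixture likelihoods can be multimodal at
    small n, hence the restarts.
    """
    errors = _as_errors(trials)
    n = errors.size
    if n < min_trials:
        raise InsufficientDataError(
            f"fit_contamination: {n} trials < floor of {min_trials}")

    starts = [_moment_start(errors)] + _START_GRID
    bounds = [(np.log(KAPPA_MIN), np.log(KAPPA_MAX)),
              (-_LOGIT_BOUND, _LOGIT_BOUND)]
    best = None
    diagnostics = []
    for k0, a0 in starts:
        z0 = np.array([np.log(k0), special.logit(a0)])
        res = optimize.minimize(_nll, z0, args=(errors,), method="L-BFGS-B",
                                bounds=bounds)
        diagnostics.append({"start": (k0, a0), "success": bool(res.success),
                            "fun": float(res.fun), "message": str(res.message)})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError(
            "fit_contamination: no restart converged", {"restarts": diagnostics})

    kappa = float(np.exp(best.x[0]))
    alpha = float(special.expit(best.x[1]))
    at_bound = (abs(best.x[0] - np.log(KAPPA_MAX)) < 1e-6
                or abs(best.x[0] - np.log(KAPPA_MIN)) < 1e-6
                or abs(abs(best.x[1]) - _LOGIT_BOUND) < 1e-6)
    return ContaminationParams(kappa_t=kappa, alpha=alpha,
                               loglik=-float(best.fun), n_trials=int(n),
                               converged=True, at_bound=at_bound)


def fit_sync_gaussian(trials, warn_sd: float = 1.0) -> SyncGaussianParams:
    """Estimate (σ_y, σ_t) from synchronous-report trials.

    σ_y is the circular SD √(−2 ln R̄) of the wrapped errors — for the
    small errors this model assumes it coincides with the linear SD while
    remaining robust to occasional wrap-around — and σ_t = σ_y/√2.
    """
    if isinstance(trials, pd.DataFrame):
        if "timing" in trials.columns and not (trials["timing"] == "synchronous").all():
            raise ValueError("fit_sync_gaussian: non-synchronous trials present")
        errors = response_errors(trials)
    else:
        errors = np.asarray(wrap(np.asarray(trials, dtype=float)))
    if errors.size == 0:
        raise InsufficientDataError("fit_sync_gaussian: no trials")
    if np.allclose(errors, 0.0):
        return SyncGaussianParams(sigma_y=0.0, sigma_t=0.0, n_trials=errors.size)
    sigma_y = circular_sd(errors)
    if sigma_y > warn_sd:
        import warnings

        warnings.warn("fit_sync_gaussian: error SD is large relative to the "
                      "circle; the linear-Gaussian reading of sigma_y is suspect",
                      stacklevel=2)
    return SyncGaussianParams(sigma_y=sigma_y, n_trials=int(errors.size))
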