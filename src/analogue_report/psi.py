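"""Adaptive PSI (Kontsevich–Tyler) foil placement for the 2-AFC task.

The procedure keeps a posterior over psychometric parameters on a finite
grid and, before each trial, picks the stimulus (foil offset |δ|) whose
outcome is expected to minimize the entropy of the updated posterior —
i.e. the most informative next trial. After the observer responds, the
posterior is updated by Bayes' rule and the loop repeats.

The psychometric family is parameterized directly as (κ, α) with the
asynchronous contamination link, so the online procedure and the
retrospective maximum-likelihood fit share one model. Grid ranges,
resolutions and the uniform prior live in :mod:`analogue_report.config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .afc import pcorr_async
from .config import default_config

__all__ = ["PsiState", "psi_init", "psi_select", "psi_update",
           "posterior_mean", "posterior_entropy", "expected_entropies"]


@dataclass(frozen=True)
class PsiState:
    """Grid posterior over (κ, α) plus the candidate-stimulus grid.

    ``posterior`` has shape ``(n_kappa, n_alpha)`` and sums to 1.
    ``lik_correct[s, i, j]`` caches Pr(correct | δ_s, κ_i, α_j).
    """

    kappa_grid: np.ndarray
    alpha_grid: np.ndarray
    stimulus_grid: np.ndarray
    posterior: np.ndarray
    trial_count: int = 0
    family: str = "async_contamination"
    lik_correct: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.kappa_grid.size == 0 or self.alpha_grid.size == 0:
            raise ValueError("PsiState: parameter grids must be nonempty")
        if self.stimulus_grid.size == 0:
            raise ValueError("PsiState: stimulus grid must be nonempty")
        if np.any(self.posterior < 0):
            raise ValueError("PsiState: posterior masses must be >= 0")
        if abs(float(self.posterior.sum()) - 1.0) > 1e-12:
            raise ValueError("PsiState: posterior must sum to 1")
        if self.lik_correct is None:
            object.__setattr__(self, "lik_correct",
                               _likelihood_table(self.stimulus_grid,
                                                 self.kappa_grid,
                                                 self.alpha_grid))


_TABLE_CACHE: dict = {}


def _likelihood_table(stimuli, kappas, alphas) -> np.ndarray:
    key = (stimuli.tobytes(), kappas.tobytes(), alphas.tobytes())
    cached = _TABLE_CACHE.get(key)
    if cached is not None:
        return cached
    S, K, A = stimuli.size, kappas.size, alphas.size
    table = np.empty((S, K, A))
    for i, kappa in enumerate(kappas):
        # alpha enters linearly: p = alpha * p1 + (1 - alpha)/2
        p1 = pcorr_async(stimuli, kappa, 1.0)
        table[:, i, :] = alphas[None, :] * np.asarray(p1)[:, None] \
            + (1.0 - alphas[None, :]) / 2.0
    table.setflags(write=False)
    if len(_TABLE_CACHE) < 8:  # bounded memo; grids rarely vary in one run
        _TABLE_CACHE[key] = table
    return table


def psi_init(config: dict | None = None, prior: np.ndarray | None = None) -> PsiState:
    """Build the initial PSI state from a config block.

    ``config`` is the ``psi`` section of the pipeline configuration (grid
    ranges/resolutions); ``prior`` overrides the uniform default and is
    normalized.
    """
    cfg = (config or default_config()["psi"])
    kappas = np.geomspace(cfg["kappa_min"], cfg["kappa_max"], int(cfg["n_kappa"]))
    alphas = np.linspace(cfg["alpha_min"], cfg["alpha_max"], int(cfg["n_alpha"]))
    n_stim = int(cfg["n_stimulus"])
    # (0, pi]: exclude the uninformative delta = 0
    stimuli = np.linspace(0.0, np.pi, n_stim + 1)[1:]
    if prior is None:
        post = np.full((kappas.size, alphas.size), 1.0 / (kappas.size * alphas.size))
    else:
        post = np.asarray(prior, dtype=float)
        if post.shape != (kappas.size, alphas.size):
            raise ValueError("psi_init: prior shape does not match the grid")
        if np.any(post < 0) or post.sum() <= 0:
            raise ValueError("psi_init: prior must be nonnegative with positive mass")
        post = post / post.sum()
    return PsiState(kappa_grid=kappas, alpha_grid=alphas, stimulus_grid=stimuli,
                    posterior=post)


def _entropy(p: np.ndarray, axis=None) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -np.sum(terms, axis=axis)


def expected_entropies(state: PsiState) -> np.ndarray:
    """Expected posterior entropy after one trial, for every candidate δ.

    For stimulus s with predictive probability of a correct response
    m_s = Σ_θ p(θ) Pr(correct | s, θ), the expectation is
    m_s · H[p(θ|correct)] + (1 − m_s) · H[p(θ|error)].
    """
    p = state.posterior.reshape(1, -1)  # (1, N)
    lik = state.lik_correct.reshape(state.stimulus_grid.size, -1)  # (S, N)
    joint_c = p * lik
    joint_w = p * (1.0 - lik)
    m_c = joint_c.sum(axis=1)
    m_w = joint_w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_c = np.where(m_c > 0, _entropy(joint_c, axis=1) / m_c + np.log(
            np.where(m_c > 0, m_c, 1.0)), 0.0)
        h_w = np.where(m_w > 0, _entropy(joint_w, axis=1) / m_w + np.log(
            np.where(m_w > 0, m_w, 1.0)), 0.0)
    return m_c * h_c + m_w * h_w


def psi_select(state: PsiState) -> float:
    """Stimulus |δ| minimizing expected posterior entropy.

    Deterministic given the state; exact ties resolve to the smallest |δ|
    (np.argmin returns the first minimum and the grid is ascending).
    """
    eh = expected_entropies(state)
    # tolerate float noise so a flat landscape ties to the smallest |delta|
    idx = int(np.argmin(np.round(eh, 12)))
    return float(state.stimulus_grid[idx])


def psi_update(state: PsiState, delta: float, correct: bool) -> PsiState:
    """Bayes update of the posterior after observing (δ, correct)."""
    d = abs(float(delta))
    matches = np.isclose(state.stimulus_grid, d, rtol=0, atol=1e-9)
    if not matches.any():
        raise ValueError(f"psi_update: delta {d!r} not on the stimulus grid")
    s = int(np.argmax(matches))
    lik = state.lik_correct[s] if correct else 1.0 - state.lik_correct[s]
    post = state.posterior * lik
    total = float(post.sum())
    if total <= 0:
        raise ValueError("psi_update: posterior mass vanished (contradictory data)")
    return replace(state, posterior=post / total, trial_count=state.trial_count + 1)


def posterior_mean(state: PsiState) -> tuple[float, float]:
    """Posterior means (κ̄, ᾱ) — the online estimates the procedure reports."""
    pk = state.posterior.sum(axis=1)
    pa = state.posterior.sum(axis=0)
    return (float(pk @ state.kappa_grid), float(pa @ state.alpha_grid))


def posterior_entropy(state: PsiState) -> float:
    return float(_entropy(state.posterior))
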