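"""Seeded synthetic observers with the statistical structure the models assume.

The generator emulates a two-experiment colour-report design: analogue
(continuous) report and PSI-driven 2-AFC, crossed with set size {1, 4},
synchronous vs asynchronous report, delay {0, 1000} ms, chroma radius
{25, 50} and — for analogue report without delay — wheel physical radius
{3, 10} dva. Responses come from the package's own generative models:

* analogue — with probability α the internal response is target + von
  Mises(κ) noise, otherwise uniform; the internal hue is then placed on a
  wheel of the trial's physical radius, displaced by isotropic 2-D
  Gaussian motor noise of SD ``sigma_motor`` dva, and read back as an
  angle (the radial component is discarded: clicks report hue only);
* 2-AFC asynchronous — the observer picks whichever of probe and foil is
  closer on the circle to a draw from the same mixture;
* 2-AFC synchronous — target, probe and foil each carry independent
  N(0, σ_t²) noise and the nearest-to-target rule decides.

Set-size and delay effects enter only through condition-indexed (κ, α)
maps; no process model of memory decay is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import wrap
from .config import default_config
from .psi import psi_init, psi_select, psi_update, posterior_mean

__all__ = [
    "ObserverParams",
    "DesignSpec",
    "condition_key",
    "lab_coords",
    "draw_mixture_errors",
    "apply_motor_noise",
    "simulate_wheel_errors",
    "simulate_analogue",
    "simulate_afc",
    "simulate_cohort",
]


def condition_key(timing: str, set_size: int, delay_ms: int) -> str:
    """Canonical key for the condition-indexed parameter maps."""
    return f"{timing}/{set_size}/{delay_ms}"


@dataclass
class ObserverParams:
    """Generating parameters of one synthetic observer."""

    observer: str = "sim01"
    kappa_by_condition: dict = field(default_factory=dict)
    alpha_by_condition: dict = field(default_factory=dict)
    sigma_t_sync: float = 0.15
    sigma_motor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for key, kappa in self.kappa_by_condition.items():
            if kappa < 0:
                raise ValueError(f"kappa must be >= 0 for condition {key}")
        for key, alpha in self.alpha_by_condition.items():
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"alpha must lie in [0, 1] for condition {key}")
        if self.sigma_motor < 0:
            raise ValueError("sigma_motor must be >= 0")
        if self.sigma_t_sync <= 0:
            raise ValueError("sigma_t_sync must be > 0")

    @classmethod
    def from_config(cls, cfg: dict | None = None, observer: str = "sim01",
                    seed: int = 0, **overrides) -> "ObserverParams":
        obs_cfg = (cfg or default_config())["observer"]
        kwargs = dict(
            observer=observer,
            kappa_by_condition=dict(obs_cfg["kappa_by_condition"]),
            alpha_by_condition=dict(obs_cfg["alpha_by_condition"]),
            sigma_t_sync=obs_cfg["sigma_t_sync"],
            sigma_motor=obs_cfg["sigma_motor"],
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class DesignSpec:
    """Factorial layout and trial counts of the simulated experiments."""

    set_sizes: tuple = (1, 4)
    timings: tuple = ("synchronous", "asynchronous")
    delays_ms: tuple = (0, 1000)
    chroma_radii: tuple = (25, 50)
    wheel_radii_dva: tuple = (3.0, 10.0)
    n_analogue_per_cond: int = 50
    n_afc_per_cond: int = 80
    n_locations: int = 8
    location_ring_radius_dva: float = 6.0
    stimulus_duration_ms: int = 500

    def __post_init__(self):
        if self.n_analogue_per_cond <= 0 or self.n_afc_per_cond <= 0:
            raise ValueError("trial counts must be positive")

    def cells(self):
        """(timing, set_size, delay_ms) cells: synchronous report is always
        a single visible item with no delay; delays apply to asynchronous
        report only."""
        out = []
        if "synchronous" in self.timings:
            out.append(("synchronous", 1, 0))
        if "asynchronous" in self.timings:
            for delay in self.delays_ms:
                for ss in self.set_sizes:
                    out.append(("asynchronous", ss, delay))
        return out

    def analogue_conditions(self):
        """Full analogue-report condition grid. The wheel-size manipulation
        belongs to the no-delay experiment; delayed conditions use the
        largest wheel only."""
        big_wheel = (max(self.wheel_radii_dva),)
        rows = []
        for timing, ss, delay in self.cells():
            radii = self.wheel_radii_dva if delay == 0 else big_wheel
            for chroma in self.chroma_radii:
                for radius in radii:
                    rows.append({"timing": timing, "set_size": ss,
                                 "delay_ms": delay, "chroma_radius": chroma,
                                 "wheel_radius_dva": float(radius)})
        return rows

    def afc_conditions(self):
        rows = []
        for timing, ss, delay in self.cells():
            for chroma in self.chroma_radii:
                rows.append({"timing": timing, "set_size": ss,
                             "delay_ms": delay, "chroma_radius": chroma})
        return rows


def lab_coords(hue, chroma_radius):
    """CIE Lab coordinates of a hue angle on the stimulus colour wheel.

    The wheel is a circle of constant luminance L = 60 centred at
    a = b = 12.5 with radius ``chroma_radius`` in the (a, b) plane.
    """
    r = float(chroma_radius)
    if r <= 0:
        raise ValueError("lab_coords: chroma radius must be positive")
    hue = np.asarray(hue, dtype=float)
    L = np.broadcast_to(60.0, hue.shape).astype(float) if hue.ndim else 60.0
    a = 12.5 + r * np.cos(hue)
    b = 12.5 + r * np.sin(hue)
    if hue.ndim:
        return L, a, b
    return float(L), float(a), float(b)


def draw_mixture_errors(kappa: float, alpha: float, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw n errors from the contamination mixture (von Mises + uniform)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("draw_mixture_errors: alpha must lie in [0, 1]")
    if kappa < 0:
        raise ValueError("draw_mixture_errors: kappa must be >= 0")
    target_related = rng.random(n) < alpha
    errors = rng.uniform(-np.pi, np.pi, n)
    n_t = int(target_related.sum())
    if n_t and kappa > 0:
        errors[target_related] = rng.vonmises(0.0, kappa, n_t)
    elif n_t:  # kappa == 0: target-related responses are uniform too
        errors[target_related] = rng.uniform(-np.pi, np.pi, n_t)
    return wrap(errors)


def apply_motor_noise(angles, wheel_radius_dva: float, sigma_motor: float,
                      rng: np.random.Generator):
    """Displace the click point by isotropic 2-D Gaussian motor noise.

    The internally selected hue is mapped to a point on the response wheel
    (radius in dva), perturbed in the display plane, and re-projected to
    an angle; the radial displacement component is discarded because a
    click reports hue only.
    """
    if sigma_motor < 0:
        raise ValueError("apply_motor_noise: sigma_motor must be >= 0")
    if wheel_radius_dva <= 0:
        raise ValueError("apply_motor_noise: wheel radius must be positive")
    angles = np.asarray(angles, dtype=float)
    if sigma_motor == 0:
        return wrap(angles)
    x = wheel_radius_dva * np.cos(angles) + rng.normal(0.0, sigma_motor, angles.shape)
    y = wheel_radius_dva * np.sin(angles) + rng.normal(0.0, sigma_motor, angles.shape)
    return wrap(np.arctan2(y, x))


def simulate_wheel_errors(kappa: float, alpha: float, sigma_motor: float,
                          wheel_radius_dva: float, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Response errors on one wheel: mixture noise then the motor stage."""
    internal = draw_mixture_errors(kappa, alpha, n, rng)
    return apply_motor_noise(internal, wheel_radius_dva, sigma_motor, rng)


def _cond_params(params: ObserverParams, timing: str, ss: int, delay: int):
    key = condition_key(timing, ss, delay)
    try:
        return params.kappa_by_condition[key], params.alpha_by_condition[key]
    except KeyError as exc:
        raise ValueError(f"ObserverParams has no entry for condition {key}") from exc


def simulate_analogue(params: ObserverParams, design: DesignSpec | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Simulate the full analogue-report trial table for one observer."""
    design = design or DesignSpec()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    chroma_order = sorted(design.chroma_radii)
    frames = []
    for cond in design.analogue_conditions():
        kappa, alpha = _cond_params(params, cond["timing"], cond["set_size"],
                                    cond["delay_ms"])
        n = design.n_analogue_per_cond
        targets = rng.uniform(-np.pi, np.pi, n)
        errors = simulate_wheel_errors(kappa, alpha, params.sigma_motor,
                                       cond["wheel_radius_dva"], n, rng)
        frames.append(pd.DataFrame({
            "observer": params.observer,
            "session": 1 + chroma_order.index(cond["chroma_radius"]),
            "task": "analogue",
            "timing": cond["timing"],
            "set_size": cond["set_size"],
            "delay_ms": cond["delay_ms"],
            "chroma_radius": cond["chroma_radius"],
            "wheel_radius_dva": cond["wheel_radius_dva"],
            "target_rad": wrap(targets),
            "response_rad": wrap(targets + errors),
        }))
    return pd.concat(frames, ignore_index=True)


def _afc_outcome(timing: str, delta: float, kappa: float, alpha: float,
                 sigma_t: float, rng: np.random.Generator) -> bool:
    if timing == "asynchronous":
        e = float(draw_mixture_errors(kappa, alpha, 1, rng)[0])
        d_probe = abs(float(wrap(e)))
        d_foil = abs(float(wrap(e - delta)))
    else:
        eps_t, eps_p, eps_f = rng.normal(0.0, sigma_t, 3)
        d_probe = abs(float(wrap(eps_p - eps_t)))
        d_foil = abs(float(wrap(delta + eps_f - eps_t)))
    if d_probe == d_foil:  # probability-zero tie: fair coin
        return bool(rng.random() < 0.5)
    return d_probe < d_foil


def simulate_afc(params: ObserverParams, design: DesignSpec | None = None,
                 psi_config: dict | None = None, seed: int | None = None):
    """Simulate PSI-driven 2-AFC trials for one observer.

    Returns ``(trials, psi_log)``: the trial table and the per-trial PSI
    run log (selected δ, outcome, online posterior means).
    """
    design = design or DesignSpec()
    psi_cfg = psi_config or default_config()["psi"]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    chroma_order = sorted(design.chroma_radii)
    trial_rows, log_rows = [], []
    for cond in design.afc_conditions():
        kappa, alpha = _cond_params(params, cond["timing"], cond["set_size"],
                                    cond["delay_ms"])
        state = psi_init(psi_cfg)
        for trial in range(design.n_afc_per_cond):
            d_abs = psi_select(state)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            delta = sign * d_abs
            correct = _afc_outcome(cond["timing"], delta, kappa, alpha,
                                   params.sigma_t_sync, rng)
            state = psi_update(state, d_abs, correct)
            k_mean, a_mean = posterior_mean(state)
            target = float(rng.uniform(-np.pi, np.pi))
            trial_rows.append({
                "observer": params.observer,
                "session": 1 + chroma_order.index(cond["chroma_radius"]),
                "timing": cond["timing"],
                "set_size": cond["set_size"],
                "delay_ms": cond["delay_ms"],
                "chroma_radius": cond["chroma_radius"],
                "target_rad": target,
                "delta_rad": delta,
                "correct": bool(correct),
            })
            log_rows.append({
                "observer": params.observer,
                "timing": cond["timing"],
                "set_size": cond["set_size"],
                "delay_ms": cond["delay_ms"],
                "chroma_radius": cond["chroma_radius"],
                "trial": trial + 1,
                "delta_rad": delta,
                "correct": bool(correct),
                "posterior_mean_kappa": k_mean,
                "posterior_mean_alpha": a_mean,
            })
    return pd.DataFrame(trial_rows), pd.DataFrame(log_rows)


def simulate_cohort(n_observers: int = 10, design: DesignSpec | None = None,
                    cfg: dict | None = None, seed: int = 0,
                    sigma_motor: float | None = None):
    """Simulate a cohort sharing generating parameters but not seeds.

    Returns ``(analogue, afc, psi_log)`` DataFrames covering
    ``n_observers`` synthetic observers.
    """
    cfg = cfg or default_config()
    design = design or DesignSpec()
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_observers)
    analogue, afc, logs = [], [], []
    for i in range(n_observers):
        overrides = {} if sigma_motor is None else {"sigma_motor": sigma_motor}
        params = ObserverParams.from_config(cfg, observer=f"sim{i + 1:02d}",
                                            seed=int(seeds[2 * i] % (2**31)),
                                            **overrides)
        analogue.append(simulate_analogue(params, design))
        t, log = simulate_afc(params, design, cfg["psi"],
                              seed=int(seeds[2 * i + 1] % (2**31)))
        afc.append(t)
        logs.append(log)
    return (pd.concat(analogue, ignore_index=True),
            pd.concat(afc, ignore_index=True),
            pd.concat(logs, ignore_index=True))
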