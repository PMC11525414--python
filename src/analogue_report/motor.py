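"""Motor-noise variance decomposition across colour-wheel physical sizes.

Hand/mouse noise is constant in display units (degrees of visual angle,
dva), so its angular footprint on a response wheel of physical radius R
shrinks as 1/R: σ_dva ≈ R σ_ang for errors small relative to the
circumference. Non-motor error, by contrast, is constant in angular
units. Comparing angular error variance on two wheels of different radii
therefore isolates the motor component:

    σ²_motor = (σ²_small − σ²_large) / (R_small⁻² − R_large⁻²).

Note on units: the decomposition is algebraic, and the canonical motor
quantity reported here is the display-unit SD σ_motor in dva. A set of
angular projections (σ_motor/R, in degrees) is internally consistent only
under that reading; ``angular_sd_from_motor`` implements it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MotorEstimate", "estimate_motor_variance", "angular_sd_from_motor"]

ANGULAR_VALID_DEG = 30.0  # beyond this the small-error linearization is suspect


@dataclass
class MotorEstimate:
    """Motor variability in display units with its per-wheel angular inputs.

    ``sigma2_motor`` (dva²) may come out negative when sampling noise
    dominates the wheel-size contrast; it is preserved and flagged rather
    than clipped, and the SD is then reported as NaN.
    """

    sigma2_small: float
    sigma2_large: float
    R_small: float
    R_large: float
    sigma2_motor: float
    negative_variance: bool = False

    @property
    def sigma_motor_dva(self) -> float:
        if self.negative_variance:
            return float("nan")
        return float(np.sqrt(self.sigma2_motor))


def estimate_motor_variance(sigma2_small: float, sigma2_large: float,
                            R_small: float = 3.0, R_large: float = 10.0) -> MotorEstimate:
    """Decompose angular error variances on two wheels into a motor component.

    Parameters
    ----------
    sigma2_small, sigma2_large : float
        Angular error variance (radians²) on the physically small and
        large wheels. Any radius-independent (non-motor) variance cancels.
    R_small, R_large : float
        Wheel physical radii in dva; must be positive and distinct with
        ``R_small < R_large``.
    """
    R_small, R_large = float(R_small), float(R_large)
    if R_small <= 0 or R_large <= 0:
        raise ValueError("estimate_motor_variance: radii must be positive")
    if R_small == R_large:
        raise ValueError("estimate_motor_variance: radii must be distinct")
    if R_small > R_large:
        raise ValueError("estimate_motor_variance: expected R_small < R_large")
    sigma2_motor = (float(sigma2_small) - float(sigma2_large)) \
        / (R_small**-2 - R_large**-2)
    return MotorEstimate(sigma2_small=float(sigma2_small),
                         sigma2_large=float(sigma2_large),
                         R_small=R_small, R_large=R_large,
                         sigma2_motor=float(sigma2_motor),
                         negative_variance=sigma2_motor < 0)


def angular_sd_from_motor(sigma_motor: float, R: float) -> float:
    """Angular SD (degrees) produced by display-unit motor SD on a wheel of radius R.

    Implements σ_ang = σ_motor / R (radians), returned in degrees. Warns
    when the projection exceeds ~30°, where the small-error linearization
    σ_dva ≈ R σ_ang stops being trustworthy.
    """
    sigma_motor, R = float(sigma_motor), float(R)
    if sigma_motor <= 0 or R <= 0:
        raise ValueError("angular_sd_from_motor: inputs must be positive")
    deg = float(np.degrees(sigma_motor / R))
    if deg > ANGULAR_VALID_DEG:
        warnings.warn(
            f"angular_sd_from_motor: {deg:.1f} deg exceeds the small-error "
            "regime of the linear radius scaling", stacklevel=2)
    return deg
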