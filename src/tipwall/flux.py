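"""Cell-wall material deposition required to maintain the thickness gradient.

In the frame travelling with the tip of a self-similarly growing cell the
wall material slides backwards along the meridian at v_m = v sin(phi)
while the surface stretches.  Conservation of wall volume in a meridional
annulus then fixes the local deposition rate (wall volume per unit surface
per unit time, i.e. µm min⁻¹):

    D(s) = v_m(s) d(delta)/ds + delta(s) (eps_s(s) + eps_theta(s)),

with the kinematic strain rates of a translating surface,
eps_s = V_n kappa_s and eps_theta = V_n kappa_theta, V_n = v cos(phi).
The first term feeds the thickening of material advected down the
gradient; the second compensates surface dilution where the wall
stretches.  Integrated over the whole surface the deposition equals the
wall volume advected out at the back, 2 pi R delta_max v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile import MeridionalProfile
from .thickness import WallGradient, evaluate_gradient

__all__ = ["FluxProfile", "deposition_rate"]


@dataclass(frozen=True)
class FluxProfile:
    s: np.ndarray  # µm
    D: np.ndarray  # µm³ wall per µm² surface per min = µm min⁻¹
    advection: np.ndarray  # v_m * d(delta)/ds component
    dilution: np.ndarray  # delta * (eps_s + eps_theta) component
    r: np.ndarray  # µm, for per-length conversion

    @property
    def per_length(self) -> np.ndarray:
        """Deposition per unit meridional length, D * 2 pi r (µm² min⁻¹)."""
        return self.D * 2.0 * np.pi * self.r

    def total(self) -> float:
        """Whole-cell deposition rate, integral of D over the surface (µm³ min⁻¹)."""
        return float(np.trapezoid(self.per_length, self.s))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s": self.s,
                "D_per_area": self.D,
                "D_per_length": self.per_length,
                "advection": self.advection,
                "dilution": self.dilution,
            }
        )


def deposition_rate(
    profile: MeridionalProfile,
    gradient: WallGradient,
    v_tip: float,
) -> FluxProfile:
    """Deposition rate D(s) maintaining ``gradient`` during self-similar growth.

    d(delta)/ds comes analytically from the fitted gradient family, not
    from finite differences.
    """
    delta = evaluate_gradient(gradient, profile.s)
    ddelta = gradient.derivative(profile.s)
    V_n = v_tip * np.cos(profile.phi)
    v_m = v_tip * np.sin(profile.phi)
    advection = v_m * ddelta
    dilution = delta * V_n * (profile.kappa_s + profile.kappa_theta)
    return FluxProfile(
        s=profile.s,
        D=advection + dilution,
        advection=advection,
        dilution=dilution,
        r=profile.r,
    )
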