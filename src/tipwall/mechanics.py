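"""Thin-shell wall stresses and viscoplastic (Lockhart) inference.

For an axisymmetric pressurized membrane of thickness ``delta`` the
in-plane stresses are

    sigma_s     = P / (2 delta kappa_theta)
    sigma_theta = P (2 kappa_theta - kappa_s) / (2 delta kappa_theta^2)

which give the familiar limits sigma_theta = sigma_s at the tip (where the
two curvatures coincide) and sigma_theta = 2 sigma_s on a cylinder.  The
scalar stress entering the yield criterion is the generalized von Mises
form sigma_e = sqrt(sigma_s^2 + sigma_theta^2 - 2 nu sigma_s sigma_theta),
with nu = 1/2 for a transversely isotropic wall.

Under self-similar growth (pure axial translation at the tip speed ``v``)
the surface moves normally at V_n = v cos(phi), the circumferential strain
rate is kinematically V_n kappa_theta, and the anisotropic flow rule
eps_theta = eps (sigma_theta - nu sigma_s)/sigma_e turns this into the
expected total strain rate

    eps* = K kappa_theta sigma_e / (sigma_theta - nu sigma_s) V_n .

If the wall is a uniform Lockhart material, eps* must be an affine
function of sigma_e with slope Phi (extensibility) and abscissa-intercept
sigma_y (yield threshold); ``lockhart_fit`` inverts that plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .profile import MeridionalProfile
from .thickness import WallGradient, evaluate_gradient

__all__ = [
    "ViscoplasticParams",
    "MechanicalState",
    "shell_stresses",
    "effective_stress",
    "normal_velocity_selfsimilar",
    "expected_strain_rate",
    "lockhart_fit",
    "pollen_wall_properties",
    "mechanical_state",
]


@dataclass(frozen=True)
class ViscoplasticParams:
    """Material and driving parameters (µm / MPa / min unit system)."""

    P: float = 0.495  # turgor, MPa
    Phi: float = 2.51e-3  # extensibility, MPa⁻¹ min⁻¹
    sigma_y: float = 11.18  # yield threshold, MPa
    nu: float = 0.5  # flow coupling; 1/2 = transverse isotropy
    K: float = 1.0  # strain-rate normalization
    v_tip: float = 2.5 / 60.0  # tip speed, µm min⁻¹ (2.5 µm h⁻¹)

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError("turgor P must be positive")
        if self.Phi < 0 or self.sigma_y < 0:
            raise ValueError("Phi and sigma_y must be non-negative")
        if not 0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 0.5]")
        if self.v_tip <= 0:
            raise ValueError("v_tip must be positive")


@dataclass(frozen=True)
class MechanicalState:
    """Per-point mechanical fields aligned with a MeridionalProfile."""

    profile: MeridionalProfile
    delta: np.ndarray  # µm
    sigma_s: np.ndarray  # MPa
    sigma_theta: np.ndarray  # MPa
    sigma_e: np.ndarray  # MPa
    V_n: np.ndarray  # µm min⁻¹
    eps_star: np.ndarray  # min⁻¹


def shell_stresses(profile: MeridionalProfile, delta, P: float):
    """Meridional and circumferential membrane stresses (MPa)."""
    delta = np.broadcast_to(np.asarray(delta, dtype=float), profile.s.shape)
    kt = profile.kappa_theta
    ks = profile.kappa_s
    if np.any(delta <= 0):
        raise ValueError("wall thickness must be positive everywhere")
    if np.any(kt <= 0):
        raise ValueError("kappa_theta must be positive everywhere")
    sigma_s = P / (2.0 * delta * kt)
    sigma_theta = P * (2.0 * kt - ks) / (2.0 * delta * kt**2)
    return sigma_s, sigma_theta


def effective_stress(sigma_s, sigma_theta, nu: float = 0.5):
    """Generalized von Mises scalar stress (plane stress at nu = 1/2)."""
    sigma_s = np.asarray(sigma_s, dtype=float)
    sigma_theta = np.asarray(sigma_theta, dtype=float)
    if not (np.all(np.isfinite(sigma_s)) and np.all(np.isfinite(sigma_theta))):
        raise ValueError("stresses must be finite")
    out = np.sqrt(sigma_s**2 + sigma_theta**2 - 2.0 * nu * sigma_s * sigma_theta)
    return float(out) if out.ndim == 0 else out


def normal_velocity_selfsimilar(profile: MeridionalProfile, v_tip: float) -> np.ndarray:
    """Normal surface speed of a profile translating axially at v_tip."""
    return v_tip * np.cos(profile.phi)


def expected_strain_rate(
    profile: MeridionalProfile,
    sigma_s: np.ndarray,
    sigma_theta: np.ndarray,
    sigma_e: np.ndarray,
    V_n: np.ndarray,
    nu: float = 0.5,
    K: float = 1.0,
    mask_invalid: bool = False,
) -> np.ndarray:
    """eps*(s) = K kappa_theta sigma_e / (sigma_theta - nu sigma_s) V_n.

    A moving point with sigma_theta - nu sigma_s <= 0 is outside the flow
    rule's domain (kappa_s > (2 - nu) kappa_theta, an overly sharp local
    bend).  On exact geometry this is a model-domain error; on measured
    (noisy) profiles pass ``mask_invalid=True`` to flag such points as NaN
    so downstream fits can exclude them.
    """
    denom = sigma_theta - nu * sigma_s
    moving = V_n > 0
    bad = moving & (denom <= 0)
    if np.any(bad) and not mask_invalid:
        raise ValueError(
            "flow-rule denominator sigma_theta - nu sigma_s <= 0 at a moving point"
        )
    out = np.zeros_like(V_n)
    ok = moving & (denom > 0)
    out[ok] = K * profile.kappa_theta[ok] * sigma_e[ok] / denom[ok] * V_n[ok]
    out[bad] = np.nan
    return out


def mechanical_state(
    profile: MeridionalProfile,
    gradient: WallGradient,
    params: ViscoplasticParams,
    mask_invalid: bool = False,
) -> MechanicalState:
    """Full stress / velocity / expected-strain-rate state under self-similarity."""
    delta = evaluate_gradient(gradient, profile.s)
    sigma_s, sigma_theta = shell_stresses(profile, delta, params.P)
    sigma_e = effective_stress(sigma_s, sigma_theta, params.nu)
    V_n = normal_velocity_selfsimilar(profile, params.v_tip)
    eps_star = expected_strain_rate(
        profile, sigma_s, sigma_theta, sigma_e, V_n, params.nu, params.K,
        mask_invalid=mask_invalid,
    )
    return MechanicalState(profile, delta, sigma_s, sigma_theta, sigma_e, V_n, eps_star)


def lockhart_fit(
    sigma_e: np.ndarray,
    eps_star: np.ndarray,
    threshold: float = 0.01,
) -> tuple[float, float, float]:
    """(Phi, sigma_y, r^2) from the increasing branch of eps*(sigma_e).

    Ordinary least squares of eps* on sigma_e restricted to points with
    eps* above ``threshold`` times its maximum (the branch where the wall
    actually yields).  A non-positive slope is reported as-is: the relation
    is then non-Lockhart and the caller decides what to make of it.
    """
    sigma_e = np.asarray(sigma_e, dtype=float)
    eps_star = np.asarray(eps_star, dtype=float)
    finite = np.isfinite(eps_star) & np.isfinite(sigma_e)
    sel = finite & (eps_star > threshold * np.nanmax(eps_star))
    if sel.sum() < 5:
        raise ValueError("fewer than 5 points above the strain-rate threshold")
    res = linregress(sigma_e[sel], eps_star[sel])
    phi = float(res.slope)
    sigma_y = float(-res.intercept / res.slope) if res.slope != 0 else float("nan")
    return phi, sigma_y, float(res.rvalue**2)


def pollen_wall_properties(sigma_e, eps_star):
    """Pointwise (Phi(s), sigma_y(s)) by equal partition of eps*.

    When a single Lockhart line does not hold (constant-thickness walls
    such as the pollen tube), the product Phi (sigma_e - sigma_y) = eps*
    is split symmetrically: Phi = sqrt(eps*) and sigma_e - sigma_y =
    sqrt(eps*), a working hypothesis giving one admissible spatial pattern.
    """
    sigma_e = np.asarray(sigma_e, dtype=float)
    eps_star = np.asarray(eps_star, dtype=float)
    if np.any(eps_star < 0):
        raise ValueError("eps* must be non-negative")
    root = np.sqrt(eps_star)
    return root, sigma_e - root
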