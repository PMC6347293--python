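"""Axisymmetric meridional profiles of tip-growing cells.

A cell is described by the half-meridian of its surface of revolution:
arc length ``s`` measured from the extreme tip, axial coordinate ``x``
(growth direction is +x, the tip sits at the largest x), distance to the
axis ``r``, the angle ``phi`` between the axis and the outward normal,
and the two principal curvatures ``kappa_s`` (meridional) and
``kappa_theta`` (circumferential).  The sign convention makes a convex
dome positive and gives, along the meridian,

    dphi/ds = kappa_s,   dr/ds = cos(phi),   dx/ds = -sin(phi),

with ``kappa_theta = sin(phi)/r`` away from the tip and the regular
limit ``kappa_theta -> kappa_s`` at the tip itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "MeridionalProfile",
    "geometry_from_points",
    "resample_curve",
    "extend_with_cylinder",
]


class ProfileError(ValueError):
    """Raised when arrays do not form a valid meridional profile."""


@dataclass(frozen=True)
class MeridionalProfile:
    """Discretized half-meridian of an axisymmetric cell (lengths in µm)."""

    s: np.ndarray
    x: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    kappa_s: np.ndarray
    kappa_theta: np.ndarray
    spacing: float = 0.05

    def __post_init__(self) -> None:
        arrays = (self.s, self.x, self.r, self.phi, self.kappa_s, self.kappa_theta)
        n = len(self.s)
        if any(len(a) != n for a in arrays):
            raise ProfileError("profile arrays must have equal length")
        if n < 3:
            raise ProfileError("profile needs at least 3 points")
        ds = np.diff(self.s)
        if np.any(ds <= 0) or not np.allclose(ds, self.spacing, rtol=1e-3, atol=1e-9):
            raise ProfileError("s must increase with constant spacing")
        if self.r[0] > 1e-6 or np.any(self.r < -1e-9):
            raise ProfileError("r must be >= 0 with r(0) = 0 at the tip")
        if abs(self.phi[0]) > 1e-6:
            raise ProfileError("phi(0) must vanish at the tip")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def tip_x(self) -> float:
        return float(self.x[0])

    def normals(self) -> np.ndarray:
        """Outward unit normals, shape (n, 2) as (n_x, n_r)."""
        return np.column_stack([np.cos(self.phi), np.sin(self.phi)])

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.r])

    def translated(self, dx: float) -> "MeridionalProfile":
        return replace(self, x=self.x + dx)

    def truncated(self, s_max: float) -> "MeridionalProfile":
        m = self.s <= s_max + 1e-9
        return replace(
            self,
            s=self.s[m], x=self.x[m], r=self.r[m],
            phi=self.phi[m], kappa_s=self.kappa_s[m], kappa_theta=self.kappa_theta[m],
        )


def _reflect_pad(x: np.ndarray, r: np.ndarray, k: int = 4):
    """Extend a half profile through the tip by mirror symmetry (r -> -r)."""
    xp = np.concatenate([x[k:0:-1], x])
    rp = np.concatenate([-r[k:0:-1], r])
    return xp, rp


def geometry_from_points(
    x: np.ndarray, r: np.ndarray, spacing: float, smooth_sigma: float = 0.0
) -> MeridionalProfile:
    """Build a profile (angles and curvatures) from equidistant (x, r) points.

    The points must run from the tip (``r[0] = 0``) into the shank with a
    constant arc spacing.  Derivatives are taken with central differences on
    the half profile mirrored through the axis of symmetry, which enforces
    ``phi(0) = 0`` and a regular tip curvature exactly.

    ``smooth_sigma`` (µm), if positive, low-passes the meridional-curvature
    estimate with a Gaussian — useful when the input points carry
    measurement noise; the simulator instead relies on its diffusive
    stability limit and keeps the estimate unfiltered.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    k = min(4, len(x) - 1)
    xp, rp = _reflect_pad(x, r, k)
    dx = np.gradient(xp, spacing, edge_order=2)[k:]
    dr = np.gradient(rp, spacing, edge_order=2)[k:]
    phi = np.unwrap(np.arctan2(-dx, dr))
    phi = phi - round(phi[0] / np.pi) * np.pi  # anchor the tip at phi = 0
    phip = np.concatenate([-phi[k:0:-1], phi])
    kappa_s = np.gradient(phip, spacing, edge_order=2)[k:]
    if smooth_sigma > 0:
        # 'mirror' at the tip boundary is the even extension the axial
        # symmetry dictates (kappa_s(-s) = kappa_s(s))
        kappa_s = gaussian_filter1d(
            kappa_s, smooth_sigma / spacing, mode="mirror"
        )
    kappa_theta = _circumferential(r, phi, kappa_s, spacing)
    s = spacing * np.arange(len(x))
    return MeridionalProfile(s, x, r, phi, kappa_s, kappa_theta, spacing)


def _circumferential(
    r: np.ndarray, phi: np.ndarray, kappa_s: np.ndarray, spacing: float
) -> np.ndarray:
    """kappa_theta = sin(phi)/r with the analytic tip limit near r = 0."""
    near_tip = r < 1.5 * spacing
    out = np.empty_like(r)
    out[near_tip] = kappa_s[near_tip]
    out[~near_tip] = np.sin(phi[~near_tip]) / r[~near_tip]
    return out


def resample_curve(
    x: np.ndarray, r: np.ndarray, spacing: float, method: str = "pchip"
):
    """Resample an ordered point sequence at constant arc length.

    Fits interpolating cubics x(t), r(t) in the chord-length parameter
    and extracts points equidistant in arc length (measured on a dense
    evaluation of the interpolant).  Returns (x_new, r_new).

    ``method='pchip'`` (monotone cubic) is the default: an ordinary
    cubic spline overshoots grid-frequency wiggles, so resampling every
    simulation step would amplify them without bound; PCHIP never
    overshoots.  ``method='spline'`` gives the classical C² spline for
    one-shot geometric use.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    dx, dr = np.diff(x), np.diff(r)
    seg = np.hypot(dx, dr)
    if np.sum(seg) <= 0:
        raise ProfileError("degenerate curve: zero length")
    chord = np.concatenate([[0.0], np.cumsum(seg)])
    # chord -> arc correction from the turning angle between segments:
    # a circular arc of chord c turning by theta has length c (1 + theta^2/24)
    theta = np.zeros_like(seg)
    ang = np.arctan2(dr, dx)
    turn = np.diff(ang)
    theta[:-1] += 0.5 * turn
    theta[1:] += 0.5 * turn
    arc = np.concatenate([[0.0], np.cumsum(seg * (1.0 + theta**2 / 24.0))])
    interp = PchipInterpolator if method == "pchip" else CubicSpline
    f = interp(chord, np.column_stack([x, r]), axis=0)
    n = int(np.floor(arc[-1] / spacing)) + 1
    t_new = np.interp(spacing * np.arange(n), arc, chord)
    out = f(t_new)
    return out[:, 0], out[:, 1]


def extend_with_cylinder(profile: MeridionalProfile, s_max: float) -> MeridionalProfile:
    """Continue a profile beyond its traced range with an analytic cylinder.

    The appended region keeps the final radius, ``phi = pi/2`` and
    ``kappa_s = 0``, so resampling and thickness evaluation never run off
    the data during long simulations.
    """
    if profile.s[-1] >= s_max:
        return profile
    n_add = int(np.ceil((s_max - profile.s[-1]) / profile.spacing))
    ds = profile.spacing * np.arange(1, n_add + 1)
    R = profile.r[-1]
    s = np.concatenate([profile.s, profile.s[-1] + ds])
    x = np.concatenate([profile.x, profile.x[-1] - ds])
    r = np.concatenate([profile.r, np.full(n_add, R)])
    phi = np.concatenate([profile.phi, np.full(n_add, np.pi / 2)])
    ks = np.concatenate([profile.kappa_s, np.zeros(n_add)])
    kt = np.concatenate([profile.kappa_theta, np.full(n_add, 1.0 / R)])
    return MeridionalProfile(s, x, r, phi, ks, kt, profile.spacing)
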