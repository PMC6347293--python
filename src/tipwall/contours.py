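"""From hand-traced cell contours to an averaged meridional profile.

Contours are ordered 2-D point sequences traced on the image plane (µm).
The pipeline smooths each contour with a smoothing spline, resamples it at
a constant arc step, locates the tip, computes the signed meridional
curvature on both sides of the tip, pools the per-cell curvature series in
sliding windows to obtain a symmetric average ``kappa_s(s)``, and finally
integrates that average back into a meridional profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, splev, splprep
from scipy.optimize import minimize_scalar

from .profile import MeridionalProfile

__all__ = [
    "RawContour",
    "ContourFormatError",
    "read_contours",
    "write_profile",
    "smooth_and_resample",
    "meridional_curvature",
    "find_tip",
    "curvature_series",
    "average_curvature_profile",
    "average_profile",
    "reconstruct_profile",
]


class ContourFormatError(ValueError):
    """Malformed contour table (missing columns, too few points, ...)."""


@dataclass(frozen=True)
class RawContour:
    """A hand-traced open polyline spanning the dome and part of the shanks."""

    cell_id: str
    points: np.ndarray  # (n, 2) in µm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourFormatError(
                f"contour {self.cell_id!r}: points must be an (n, 2) array"
            )
        if len(pts) < 20:
            raise ContourFormatError(
                f"contour {self.cell_id!r}: needs >= 20 points, got {len(pts)}"
            )
        object.__setattr__(self, "points", pts)


def read_contours(path: str | Path) -> list[RawContour]:
    """Read a CSV/TSV table with columns cell_id, u, v (µm) into contours.

    Point order within each cell is preserved; exactly repeated consecutive
    points (a common tracing artifact) are dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"cell_id", "u", "v"} - set(df.columns)
    if missing:
        raise ContourFormatError(
            f"{path}: missing column(s) {sorted(missing)}; need cell_id, u, v"
        )
    contours = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        pts = grp[["u", "v"]].to_numpy(dtype=float)
        keep = np.concatenate([[True], np.any(np.diff(pts, axis=0) != 0, axis=1)])
        pts = pts[keep]
        if len(pts) < 20:
            raise ContourFormatError(
                f"{path}: cell {cell_id!r} has {len(pts)} usable points (< 20)"
            )
        contours.append(RawContour(str(cell_id), pts))
    return contours


def write_profile(profile: MeridionalProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "s": profile.s,
            "x": profile.x,
            "r": profile.r,
            "phi": profile.phi,
            "kappa_s": profile.kappa_s,
            "kappa_theta": profile.kappa_theta,
        }
    ).to_csv(path, index=False)


def _fit_smoothing_spline(points: np.ndarray, smoothing: float | None):
    """Parametric smoothing spline through an ordered point set.

    ``smoothing`` is the spline residual-sum budget (µm²).  When None it is
    set automatically to ``n * sigma^2`` with the tracing noise ``sigma``
    estimated from second differences of the points (for a densely traced
    smooth curve the second difference is noise-dominated, with variance
    ``6 sigma^2`` per coordinate).
    """
    pts = points.T
    if smoothing is None:
        # tracing jitter acts along the local normal, so the squared second
        # difference summed over both coordinates is ~ 6 sigma^2 chi^2_1;
        # the chi^2_1 median is 0.455, giving the 2.73 calibration
        d2 = np.diff(points, n=2, axis=0)
        sigma2 = float(np.median(np.sum(d2**2, axis=1)) / 2.73)
        smoothing = len(points) * sigma2
    chord = np.concatenate(
        [[0.0], np.cumsum(np.hypot(*np.diff(points, axis=0).T))]
    )
    tck, _ = splprep(pts, u=chord, s=smoothing, k=3)
    return tck, chord[-1]


def smooth_and_resample(
    contour: RawContour | np.ndarray,
    spacing: float = 0.05,
    smoothing: float | None = None,
) -> np.ndarray:
    """Equidistant points (arc step ``spacing``) along the smoothed contour."""
    pts = contour.points if isinstance(contour, RawContour) else np.asarray(contour)
    length = np.sum(np.hypot(*np.diff(pts, axis=0).T))
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > length / 10:
        raise ValueError(
            f"spacing {spacing} too coarse for a contour of length {length:.3g}"
        )
    tck, t_end = _fit_smoothing_spline(pts, smoothing)
    # dense pass: map the chord parameter to arc length along the spline
    t = np.linspace(0.0, t_end, max(8 * len(pts), 800))
    xd, yd = splev(t, tck)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(xd), np.diff(yd)))])
    n = int(np.floor(arc[-1] / spacing)) + 1
    t_new = np.interp(spacing * np.arange(n), arc, t)
    return np.column_stack(splev(t_new, tck))


def meridional_curvature(points: np.ndarray) -> np.ndarray:
    """Signed curvature (µm⁻¹) along an equidistant point sequence.

    Computed from first and second derivatives of the interpolating cubic
    spline.  The overall sign is fixed so that the total turn is positive,
    making a convex dome (and a circle, whichever way it was traced)
    positive.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 5:
        raise ValueError("need at least 5 points for curvature")
    t = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    fx = CubicSpline(t, pts[:, 0])
    fy = CubicSpline(t, pts[:, 1])
    x1, y1 = fx(t, 1), fy(t, 1)
    x2, y2 = fx(t, 2), fy(t, 2)
    kappa = (x1 * y2 - y1 * x2) / (x1 * x1 + y1 * y1) ** 1.5
    if np.trapezoid(kappa, t) < 0:
        kappa = -kappa
    return kappa


def find_tip(points: np.ndarray) -> int:
    """Index of the tip on an equidistant contour point sequence.

    First guess: the point farthest from the chord joining the contour
    endpoints.  Refinement: extremum of the projection onto the principal
    (chord-normal) axis of the spline, snapped back to the nearest sample.
    """
    pts = np.asarray(points, dtype=float)
    a, b = pts[0], pts[-1]
    chord = b - a
    norm = np.hypot(*chord)
    if norm < 1e-12:
        d = np.hypot(*(pts - a).T)
    else:
        rel = pts - a
        d = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
    i0 = int(np.argmax(d))
    # refine along the axis normal to the chord through the farthest point
    if norm >= 1e-12:
        axis = np.array([-chord[1], chord[0]]) / norm
        sign = np.sign(np.dot(pts[i0] - a, axis)) or 1.0
        t = np.arange(len(pts), dtype=float)
        fx = CubicSpline(t, pts[:, 0])
        fy = CubicSpline(t, pts[:, 1])

        def neg_proj(u):
            p = np.array([fx(u), fy(u)])
            return -sign * np.dot(p - a, axis)

        lo, hi = max(i0 - 2, 0), min(i0 + 2, len(pts) - 1)
        res = minimize_scalar(neg_proj, bounds=(lo, hi), method="bounded")
        i0 = int(round(float(res.x)))
    return i0


def curvature_series(
    contour: RawContour,
    spacing: float = 0.05,
    smoothing: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed-abscissa curvature series (s, kappa_s) with the tip at s = 0.

    ``s`` runs negative on one side of the tip and positive on the other;
    the curvature sign convention makes the convex dome positive.
    """
    pts = smooth_and_resample(contour, spacing=spacing, smoothing=smoothing)
    kappa = meridional_curvature(pts)
    i_tip = find_tip(pts)
    s = spacing * (np.arange(len(pts)) - i_tip)
    return s, kappa


def average_curvature_profile(
    series: Sequence[tuple[np.ndarray, np.ndarray]],
    window: float = 0.2,
    step: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric mean curvature from per-cell two-sided series.

    For each grid distance ``|s| = k * step`` a window of width ``window``
    slides on both sides of the tip of every cell; all curvature values
    falling in either window are pooled, and their mean and standard
    deviation are reported.  The grid is truncated to the range covered by
    at least two pooled values.
    """
    if not series:
        raise ValueError("no curvature series given")
    s_all = np.concatenate([np.abs(s) for s, _ in series])
    k_all = np.concatenate([k for _, k in series])
    s_reach = max(np.max(np.abs(s)) for s, _ in series)
    grid = step * np.arange(int(np.floor(s_reach / step)) + 1)
    mean = np.full(len(grid), np.nan)
    sd = np.full(len(grid), np.nan)
    half = window / 2.0
    for i, sc in enumerate(grid):
        sel = np.abs(s_all - sc) <= half
        vals = k_all[sel]
        if len(vals) >= 2:
            mean[i] = vals.mean()
            sd[i] = vals.std(ddof=1)
    ok = ~np.isnan(mean)
    if not ok.all():
        last = np.argmax(~ok) if (~ok).any() else len(grid)
        warnings.warn(
            "curvature grid truncated to the range covered by the data",
            stacklevel=2,
        )
    stop = len(grid) if ok.all() else int(np.argmax(~ok))
    return grid[:stop], mean[:stop], sd[:stop]


def average_profile(
    contours: Sequence[RawContour],
    spacing: float = 0.05,
    window: float = 0.2,
    smoothing: float | None = None,
    trim_tail: float = 0.5,
    curvature_smoothing: float = 0.5,
) -> MeridionalProfile:
    """Averaged symmetric meridional profile from traced contours.

    Chains smoothing/resampling, per-cell curvature, two-sided window
    pooling and reconstruction.  The last ``trim_tail`` µm of the pooled
    grid are dropped (only the farthest-reaching contours contribute
    there) and the pooled mean curvature is low-passed at
    ``curvature_smoothing`` µm — the windowed mean still carries sampling
    noise at the grid scale while genuine curvature features are several
    µm wide.
    """
    from scipy.ndimage import gaussian_filter1d

    series = [
        curvature_series(c, spacing=spacing, smoothing=smoothing)
        for c in contours
    ]
    grid, mean_k, _ = average_curvature_profile(series, window=window, step=spacing)
    keep = max(int(np.ceil((grid[-1] - trim_tail) / spacing)), 10)
    mean_k = mean_k[:keep]
    if curvature_smoothing > 0:
        mean_k = gaussian_filter1d(
            mean_k, curvature_smoothing / spacing, mode="mirror"
        )
    return reconstruct_profile(grid[:keep], mean_k, spacing=spacing)


def reconstruct_profile(
    s_grid: np.ndarray,
    kappa_s: np.ndarray,
    spacing: float = 0.05,
) -> MeridionalProfile:
    """Integrate kappa_s(s) from the tip into a meridional profile.

    Solves dphi/ds = kappa_s, dr/ds = cos(phi), dx/ds = -sin(phi) from
    (s=0, r=0, phi=0, x=0) with a fixed-step 4th-order Runge-Kutta scheme
    at ``spacing``; kappa_s between grid points is interpolated with a
    cubic spline.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    kappa_s = np.asarray(kappa_s, dtype=float)
    if kappa_s[0] <= 0:
        raise ValueError("tip curvature kappa_s(0) must be positive")
    kfun = CubicSpline(s_grid, kappa_s)

    n = int(np.floor(s_grid[-1] / spacing)) + 1
    s = spacing * np.arange(n)
    phi = np.empty(n)
    r = np.empty(n)
    x = np.empty(n)
    phi[0], r[0], x[0] = 0.0, 0.0, 0.0
    h = spacing
    for i in range(n - 1):
        si, yi = s[i], np.array([phi[i], r[i], x[i]])

        def f(ss, y):
            return np.array([kfun(ss), np.cos(y[0]), -np.sin(y[0])])

        k1 = f(si, yi)
        k2 = f(si + h / 2, yi + h / 2 * k1)
        k3 = f(si + h / 2, yi + h / 2 * k2)
        k4 = f(si + h, yi + h * k3)
        phi[i + 1], r[i + 1], x[i + 1] = yi + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    if np.any(r[1:] <= 0):
        raise ValueError("inconsistent curvature: reconstructed r <= 0")
    ks = kfun(s)
    near = r < 1.5 * spacing
    kt = np.empty(n)
    kt[near] = ks[near]
    kt[~near] = np.sin(phi[~near]) / r[~near]
    return MeridionalProfile(s, x, r, phi, ks, kt, spacing)
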