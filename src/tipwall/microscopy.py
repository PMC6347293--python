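"""Bead-trajectory orthogonality and FRAP recovery statistics.

Surface-attached fluorescent beads are advected by wall expansion; if
growth is orthogonal to the surface, a bead trajectory crosses every later
cell contour at right angles.  ``trajectory_angles`` measures those
crossing angles from the spline tangents of trajectory and contour.

FRAP traces are corrected for background and spontaneous photobleaching
(monitored in an unbleached region) and fitted with a single-exponential
recovery Y(t) = Y0 + alpha (1 - exp(-t/tau)); the normalized initial
slope 1/tau serves as an exocytosis / membrane-turnover proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq, curve_fit
from scipy.stats import pearsonr

log = logging.getLogger(__name__)

__all__ = [
    "BeadTrack",
    "FrapTrace",
    "FrapFitError",
    "trajectory_angles",
    "frap_correct",
    "frap_fit",
]


@dataclass(frozen=True)
class BeadTrack:
    bead_id: str
    t: np.ndarray  # min
    points: np.ndarray  # (n, 2), µm

    def __post_init__(self) -> None:
        if len(self.t) < 2:
            raise ValueError(f"bead {self.bead_id!r}: need >= 2 time points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"bead {self.bead_id!r}: times must increase")


@dataclass
class FrapTrace:
    zone: str
    t: np.ndarray  # s, bleach at 0
    raw: np.ndarray
    background: np.ndarray
    unbleached: np.ndarray
    corrected: np.ndarray | None = field(default=None)


class FrapFitError(RuntimeError):
    pass


def _spline2d(points: np.ndarray, monotone: bool = False):
    """Parametric interpolant; monotone (PCHIP) for sparse noisy tracks,
    whose ordinary-spline tangents would wiggle between observations."""
    t = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(points, axis=0).T))])
    cls = PchipInterpolator if monotone else CubicSpline
    return cls(t, points[:, 0]), cls(t, points[:, 1]), t


def _crossings(track_pts, contour_pts):
    """Signed-distance zero crossings of a trajectory through a contour.

    The contour is treated as a dividing curve; the trajectory's signed
    distance to it changes sign at a true crossing (tangential contacts do
    not cross and are skipped).
    Returns a list of (u_track, u_contour) spline parameters.
    """
    fx, fy, tt = _spline2d(track_pts, monotone=True)
    cx, cy, tc = _spline2d(contour_pts)
    uc_dense = np.linspace(tc[0], tc[-1], 40 * len(contour_pts))
    cpts = np.column_stack([cx(uc_dense), cy(uc_dense)])
    c_tan = np.column_stack([cx(uc_dense, 1), cy(uc_dense, 1)])

    def signed_dist(u):
        p = np.array([fx(u), fy(u)])
        d2 = np.sum((cpts - p) ** 2, axis=1)
        i = int(np.argmin(d2))
        diff = p - cpts[i]
        return float(c_tan[i, 0] * diff[1] - c_tan[i, 1] * diff[0]), i

    u_dense = np.linspace(tt[0], tt[-1], max(50, 20 * len(track_pts)))
    vals = np.array([signed_dist(u)[0] for u in u_dense])
    hits = []
    for k in np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        u0 = brentq(lambda u: signed_dist(u)[0], u_dense[k], u_dense[k + 1])
        _, i = signed_dist(u0)
        hits.append((float(u0), float(uc_dense[i])))
    return hits, (fx, fy), (cx, cy)


def trajectory_angles(
    tracks: list[BeadTrack],
    contours: list[np.ndarray],
    tips: list[int] | None = None,
) -> pd.DataFrame:
    """Crossing angles between bead trajectories and cell contours.

    ``contours`` are ordered point arrays (one per observed time); ``tips``
    optionally gives the tip index of each contour so the meridional
    abscissa |s| of each crossing can be reported (otherwise the contour
    midpoint is used as the tip).  Angles are reported unfolded in
    (0, pi), between the trajectory direction (increasing time) and the
    contour tangent (increasing point index).

    Returns a DataFrame with columns bead_id, contour_index, angle_rad,
    abs_s_um.
    """
    rows = []
    for track in tracks:
        for ci, cpts in enumerate(contours):
            try:
                hits, (fx, fy), (cx, cy) = _crossings(track.points, cpts)
            except Exception as err:
                log.debug("track %s / contour %d: %s", track.bead_id, ci, err)
                continue
            if not hits:
                log.debug(
                    "track %s does not cross contour %d (tangential contact?)",
                    track.bead_id, ci,
                )
                continue
            chord = np.concatenate(
                [[0.0], np.cumsum(np.hypot(*np.diff(cpts, axis=0).T))]
            )
            i_tip = tips[ci] if tips is not None else len(cpts) // 2
            s_tip = chord[i_tip]
            for u_t, u_c in hits:
                tv = np.array([fx(u_t, 1), fy(u_t, 1)])
                cv = np.array([cx(u_c, 1), cy(u_c, 1)])
                cosang = np.dot(tv, cv) / (np.linalg.norm(tv) * np.linalg.norm(cv))
                angle = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
                rows.append(
                    {
                        "bead_id": track.bead_id,
                        "contour_index": ci,
                        "angle_rad": angle,
                        "abs_s_um": abs(float(u_c) - s_tip),
                    }
                )
    return pd.DataFrame(rows)


def angle_summary(table: pd.DataFrame) -> dict[str, float]:
    """Mean/sd of the crossing angles and Pearson r against |s|."""
    r, _ = pearsonr(table["angle_rad"], table["abs_s_um"])
    return {
        "n": float(len(table)),
        "mean_rad": float(table["angle_rad"].mean()),
        "sd_rad": float(table["angle_rad"].std(ddof=1)),
        "pearson_r_vs_abs_s": float(r),
    }


def frap_correct(
    raw: np.ndarray, background: np.ndarray, unbleached: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Background- and photobleaching-corrected FRAP signal.

    A_c(t) = (A(t) - Z(t) - (A(0) - Z(0))) * (U(0) - Z(0)) / (U(t) - Z(t)),
    where index 0 refers to the bleach time t = 0.  By construction
    A_c(0) = 0; the U-ratio undoes the spontaneous fluorescence decay.
    """
    t = np.asarray(t, dtype=float)
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    unbleached = np.asarray(unbleached, dtype=float)
    i0 = int(np.argmin(np.abs(t)))
    if np.any(unbleached <= background):
        raise ValueError("correction undefined: U(t) <= Z(t); trace rejected")
    scale = (unbleached[i0] - background[i0]) / (unbleached - background)
    return (raw - background - (raw[i0] - background[i0])) * scale


def frap_fit(
    t: np.ndarray, corrected: np.ndarray, tau_cap: float = 1e4
) -> dict[str, float]:
    """Exponential-recovery fit of the corrected post-bleach signal.

    Fits Y(t) = Y0 + alpha (1 - exp(-t/tau)) on t >= 0 by nonlinear least
    squares and reports Y0, alpha, tau (s), slope0 = 1/tau (s⁻¹) and the
    residual standard error.  Fits hitting the ``tau_cap`` bound (a flat,
    non-recovering trace) are flagged degenerate.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(corrected, dtype=float)
    post = t >= 0
    if post.sum() < 10:
        raise FrapFitError("need at least 10 post-bleach points")
    tp, yp = t[post], y[post]

    def model(tt, y0, alpha, tau):
        return y0 + alpha * (1.0 - np.exp(-tt / tau))

    span = float(yp.max() - yp.min())
    last_err = None
    for tau0 in (np.median(tp[tp > 0]) or 1.0, 1.0, 10.0):
        try:
            popt, _ = curve_fit(
                model, tp, yp,
                p0=[yp[0], max(span, 1e-9), tau0],
                bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, tau_cap]),
                maxfev=20000,
            )
            break
        except RuntimeError as err:
            last_err = err
    else:
        raise FrapFitError(f"recovery fit did not converge: {last_err}")
    y0, alpha, tau = (float(v) for v in popt)
    resid = yp - model(tp, *popt)
    rse = float(np.sqrt(np.sum(resid**2) / max(len(tp) - 3, 1)))
    # tau pegged at its cap, or an amplitude indistinguishable from the
    # residual noise: the trace does not recover and tau is meaningless
    degenerate = tau >= 0.99 * tau_cap or alpha <= 5.0 * rse
    return {
        "Y0": y0,
        "alpha": alpha,
        "tau": tau,
        "slope0": 1.0 / tau,
        "rse": rse,
        "degenerate": bool(degenerate),
    }
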