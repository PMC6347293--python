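"""Forward simulation of viscoplastic tip growth.

The wall is discretized as a half-meridian at constant arc spacing.  Each
step computes the thin-shell stresses from turgor, local curvature and the
thickness gradient (re-anchored at the current tip so the thickness field
travels with it), converts them to a normal velocity with the anisotropic
Lockhart flow rule

    V_n = Phi (sigma_e - sigma_y) (sigma_theta - nu sigma_s) / (sigma_e kappa_theta)

wherever sigma_e > sigma_y (zero below yield), displaces every point along
its outward normal for the time it takes the tip to advance by one inner
step, and resamples the displaced points on a cubic interpolating spline.
Self-similarity of a run is scored by rD, the dome-weighted mean distance
between the final contour and the initial one translated at the expected
speed.

``steady_state_profile`` constructs the exact fixed point of these
dynamics: the shape whose flow-rule velocity field coincides with a rigid
axial translation, obtained by solving pointwise for the meridional
curvature.  It is the natural initial condition for validating the
simulator and the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .mechanics import (
    ViscoplasticParams,
    effective_stress,
    lockhart_fit,
    mechanical_state,
    shell_stresses,
)
from .profile import MeridionalProfile, geometry_from_points, resample_curve
from .thickness import WallGradient, evaluate_gradient

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "StalledGrowthError",
    "GeometryFailure",
    "step",
    "simulate",
    "residual_distance",
    "optimize_parameters",
    "scan_parameters",
    "steady_state_profile",
]


class StalledGrowthError(RuntimeError):
    """The tip is below yield: the simulation cannot advance."""


class GeometryFailure(RuntimeError):
    """The contour self-intersected (non-monotone axial coordinate)."""

    def __init__(self, message: str, last_profile: MeridionalProfile):
        super().__init__(message)
        self.last_profile = last_profile


@dataclass(frozen=True)
class SimulationConfig:
    params: ViscoplasticParams = field(default_factory=ViscoplasticParams)
    gradient: WallGradient = field(
        default_factory=lambda: WallGradient("pearson", 0.0362, 0.591, 16.81)
    )
    spacing: float = 0.05  # µm between contour points
    tip_step: float = 0.001  # µm of max tip advance per inner step
    record_every: float = 0.04  # µm of tip advance between recorded frames
    target_distance: float = 25.0  # µm of total tip advance
    rd_weight_halfwidth: float = 1.0  # µm, half-weight scale of the rD weight
    cfl: float = 0.8  # stability fraction of the diffusive time-step limit
    s_window: float | None = None  # µm; if set, truncate the profile to
    # this meridional distance behind the current tip after every step,
    # and blend the flow-rule velocity into the kinematic translation
    # field (tip speed x cos phi) over the rearmost 4 µm of the window.
    # The discarded far flank cannot influence the dome (material advects
    # backwards out of the window), while its high velocity-curvature
    # sensitivity would otherwise strangle the stability time step; the
    # kinematic rear band gives the cut a stable, translation-consistent
    # boundary.

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not (self.tip_step <= self.record_every <= self.target_distance):
            raise ValueError("need tip_step <= record_every <= target_distance")


@dataclass
class SimulationResult:
    frames: list[MeridionalProfile]
    times: np.ndarray  # min, aligned with frames
    tip_positions: np.ndarray  # µm of tip advance, aligned with frames
    rD: float  # µm
    log_rD: float  # natural log; -inf when rD == 0
    stalled: bool = False

    @property
    def final(self) -> MeridionalProfile:
        return self.frames[-1]

    @property
    def elapsed(self) -> float:
        return float(self.times[-1])


def _normal_velocity(
    profile: MeridionalProfile, gradient: WallGradient, p: ViscoplasticParams
) -> np.ndarray:
    delta = evaluate_gradient(gradient, profile.s)
    sigma_s, sigma_theta = shell_stresses(profile, delta, p.P)
    sigma_e = effective_stress(sigma_s, sigma_theta, p.nu)
    V_n = np.zeros(len(profile))
    yielding = sigma_e > p.sigma_y
    V_n[yielding] = (
        p.Phi
        * (sigma_e[yielding] - p.sigma_y)
        * (sigma_theta[yielding] - p.nu * sigma_s[yielding])
        / (sigma_e[yielding] * profile.kappa_theta[yielding])
    )
    return V_n


def _kappa_sensitivity(
    profile: MeridionalProfile,
    gradient: WallGradient,
    p: ViscoplasticParams,
    eps: float = 1e-4,
    weights: np.ndarray | None = None,
) -> float:
    """max |dV_n / d kappa_s|: the effective surface-diffusion coefficient.

    Curvature-dependent normal motion is diffusive (a locally sharper spot
    carries less hoop stress, yields slower, and is caught up by its
    neighbours); an explicit step is stable only below the corresponding
    CFL limit dt < spacing^2 / (2 D).  ``weights`` scales the per-point
    sensitivity by the fraction of the velocity that actually follows the
    flow rule."""
    perturbed = replace(profile, kappa_s=profile.kappa_s + eps)
    dV = _normal_velocity(perturbed, gradient, p) - _normal_velocity(
        profile, gradient, p
    )
    if weights is not None:
        dV = dV * weights
    return float(np.max(np.abs(dV)) / eps)


def step(
    profile: MeridionalProfile, cfg: SimulationConfig
) -> tuple[MeridionalProfile, float]:
    """One inner step: displace along normals, respline, resample.

    Returns the new profile and the elapsed time dt (min), chosen so the
    tip advances by ``cfg.tip_step`` — or less when the diffusive
    stability limit binds.
    """
    V_n = _normal_velocity(profile, cfg.gradient, cfg.params)
    if V_n[0] <= 0:
        raise StalledGrowthError("sigma_e <= sigma_y at the tip: growth stalled")
    blend_w = None
    if cfg.s_window is not None:
        lo, hi = cfg.s_window - 4.0, cfg.s_window - 2.0
        blend_w = np.clip((hi - profile.s) / (hi - lo), 0.0, 1.0)
        V_n = blend_w * V_n + (1.0 - blend_w) * V_n[0] * np.cos(profile.phi)
    D = _kappa_sensitivity(profile, cfg.gradient, cfg.params, weights=blend_w)
    dt = cfg.tip_step / V_n[0]
    if D > 0:
        dt = min(dt, cfg.cfl * cfg.spacing**2 / (2.0 * D))
    disp = V_n * dt
    x_new = profile.x + disp * np.cos(profile.phi)
    r_new = profile.r + disp * np.sin(profile.phi)
    # Re-locate the apex from the displaced near-tip points: the axial
    # intercept of the symmetry parabola x = a + b r^2 through them.  A
    # pinned tip point with its own velocity estimate accumulates a
    # sub-nm ordering bias against its neighbours over thousands of
    # steps; deriving the apex from the neighbourhood removes that drift.
    n_fit = int(np.searchsorted(r_new[1:], 8 * cfg.spacing)) + 1
    rr = r_new[1:n_fit]
    A = np.column_stack([np.ones(n_fit - 1), rr**2, rr**4])
    coef, *_ = np.linalg.lstsq(A, x_new[1:n_fit], rcond=None)
    x_new[0], r_new[0] = float(coef[0]), 0.0
    x_res, r_res = resample_curve(x_new, r_new, cfg.spacing)
    if cfg.s_window is not None:
        n_keep = int(cfg.s_window / cfg.spacing) + 1
        x_res, r_res = x_res[:n_keep], r_res[:n_keep]
        if len(x_res) < n_keep:
            # rear of the window starved (static shank): replenish by
            # continuing along the end tangent
            tx, tr = x_res[-1] - x_res[-2], r_res[-1] - r_res[-2]
            norm = np.hypot(tx, tr)
            k = np.arange(1, n_keep - len(x_res) + 1) * cfg.spacing / norm
            x_res = np.concatenate([x_res, x_res[-1] + k * tx])
            r_res = np.concatenate([r_res, np.maximum(r_res[-1] + k * tr, 0.0)])
    # folding shows up away from the tip; the first ~1 µm is dominated by
    # the quadratic apex geometry where diff(x) ~ spacing^2
    j0 = int(1.0 / cfg.spacing)
    if np.any(np.diff(x_res)[j0:] > cfg.spacing * 1e-3):
        raise GeometryFailure(
            "self-intersection: x is not monotone along the resampled contour",
            profile,
        )
    return geometry_from_points(x_res, r_res, cfg.spacing), dt


def residual_distance(
    final: MeridionalProfile,
    reference: MeridionalProfile,
    translation: float,
    half_width: float = 1.0,
) -> tuple[float, float]:
    """Dome-weighted mean distance between same-s points of two profiles.

    The reference is translated axially by ``translation``; the planar
    distance d(s) between points sharing a meridional abscissa is averaged
    with weights w(s) = exp(-(s/half_width)^2 ln 2), which emphasize the
    dome.  Returns (rD, ln rD); a perfect match reports ln rD = -inf.
    """
    s = final.s[final.s <= reference.s[-1] + 1e-9]
    if len(s) == 0:
        raise ValueError("profiles have no overlapping s range")
    x_ref = np.interp(s, reference.s, reference.x) + translation
    r_ref = np.interp(s, reference.s, reference.r)
    d = np.hypot(final.x[: len(s)] - x_ref, final.r[: len(s)] - r_ref)
    w = np.exp(-((s / half_width) ** 2) * np.log(2.0))
    rD = float(np.sum(w * d) / np.sum(w))
    log_rD = float(np.log(rD)) if rD > 0 else float("-inf")
    return rD, log_rD


def simulate(initial: MeridionalProfile, cfg: SimulationConfig) -> SimulationResult:
    """Advance the tip by ``cfg.target_distance``, recording frames.

    Frames are stored every ``cfg.record_every`` of tip advance.  The
    self-similarity score compares the final contour with the initial one
    translated at the expected tip speed (``v_tip * elapsed``), so both a
    wrong final shape and a wrong growth rate raise rD.  A stalled run
    returns the frames so far with ``stalled=True`` and infinite rD.
    """
    p = cfg.params
    profile = initial
    x0 = initial.tip_x
    frames = [initial]
    times = [0.0]
    tips = [0.0]
    t = 0.0
    next_record = cfg.record_every
    stalled = False
    while profile.tip_x - x0 < cfg.target_distance - 1e-12:
        try:
            profile, dt = step(profile, cfg)
        except StalledGrowthError:
            stalled = True
            break
        t += dt
        advance = profile.tip_x - x0
        if advance >= next_record - 1e-12 or advance >= cfg.target_distance - 1e-12:
            frames.append(profile)
            times.append(t)
            tips.append(advance)
            next_record += cfg.record_every
    if stalled:
        return SimulationResult(
            frames, np.asarray(times), np.asarray(tips),
            float("inf"), float("inf"), stalled=True,
        )
    rD, log_rD = residual_distance(
        frames[-1], initial, p.v_tip * t, cfg.rd_weight_halfwidth
    )
    return SimulationResult(frames, np.asarray(times), np.asarray(tips), rD, log_rD)


def _objective(
    initial: MeridionalProfile, cfg: SimulationConfig
) -> Callable[[float, float], float]:
    def run(phi: float, sigma_y: float) -> float:
        params = replace(cfg.params, Phi=phi, sigma_y=sigma_y)
        try:
            res = simulate(initial, replace(cfg, params=params))
        except GeometryFailure:
            return float("inf")
        return res.log_rD

    return run


def optimize_parameters(
    initial: MeridionalProfile,
    cfg: SimulationConfig,
    start: tuple[float, float] | None = None,
    initial_step: float = 0.05,
    tol: float = 1e-3,
    max_evals: int = 120,
) -> tuple[float, float, float]:
    """Descent on log(rD) over (Phi, sigma_y) by compass search in log space.

    ``start`` defaults to the Lockhart regression on the initial profile's
    mechanical state.  Each sweep probes a fixed step up and down along
    each log-parameter axis in deterministic order (Phi then sigma_y) and
    moves to the first improvement; when a full sweep fails to improve,
    the step is halved.  The objective surface is a narrow curved valley
    (the rate-matching condition), where this probe-and-halve descent is
    far more robust than a finite-difference gradient.  Stops when the
    step falls below ``tol`` (relative) or the evaluation budget is spent.
    Returns (Phi, sigma_y, log_rD) at the optimum.
    """
    if start is None:
        mech = mechanical_state(initial, cfg.gradient, cfg.params)
        phi0, sy0, _ = lockhart_fit(mech.sigma_e, mech.eps_star)
        if phi0 <= 0 or sy0 <= 0:
            raise ValueError("Lockhart start is non-physical; supply start=")
        start = (phi0, sy0)
    run = _objective(initial, cfg)
    theta = np.log(np.asarray(start, dtype=float))
    f0 = run(*np.exp(theta))
    n_eval = 1
    step = initial_step
    while step >= tol and n_eval < max_evals:
        improved = False
        for i in (0, 1):  # Phi first, then sigma_y
            for sign in (+1.0, -1.0):
                cand = theta.copy()
                cand[i] += sign * step
                fc = run(*np.exp(cand))
                n_eval += 1
                if fc < f0:
                    theta, f0 = cand, fc
                    improved = True
                    break
                if n_eval >= max_evals:
                    break
            if n_eval >= max_evals:
                break
        if not improved:
            step /= 2.0
    phi_opt, sy_opt = np.exp(theta)
    return float(phi_opt), float(sy_opt), float(f0)


def scan_parameters(
    initial: MeridionalProfile,
    cfg: SimulationConfig,
    phi_grid: Sequence[float],
    sigma_y_grid: Sequence[float],
) -> np.ndarray:
    """log(rD) matrix over a parameter grid; rows = Phi, columns = sigma_y.

    Each cell is one full target-distance simulation; stalled cells are
    reported as +inf.
    """
    run = _objective(initial, cfg)
    out = np.empty((len(phi_grid), len(sigma_y_grid)))
    for i, phi in enumerate(phi_grid):
        for j, sy in enumerate(sigma_y_grid):
            out[i, j] = run(float(phi), float(sy))
    return out


# ---------------------------------------------------------------------------
# steady-state (self-similar) profile construction


def _tip_curvature_steady(gradient: WallGradient, p: ViscoplasticParams) -> float:
    """Tip curvature of the self-similar shape (positive root of a quadratic)."""
    delta0 = evaluate_gradient(gradient, 0.0)
    q = np.sqrt(2.0 - 2.0 * p.nu)
    c = p.Phi * (1.0 - p.nu) / q
    # v k^2 + c sigma_y k - c q P / (2 delta0) = 0
    a, b, cc = p.v_tip, c * p.sigma_y, -c * q * p.P / (2.0 * delta0)
    disc = b * b - 4.0 * a * cc
    k = (-b + np.sqrt(disc)) / (2.0 * a)
    if k <= 0:
        raise StalledGrowthError("no growing self-similar tip for these parameters")
    return float(k)


def steady_state_profile(
    gradient: WallGradient,
    params: ViscoplasticParams,
    spacing: float = 0.05,
    s_max: float = 40.0,
) -> MeridionalProfile:
    """Shape whose viscoplastic normal velocity equals an axial translation.

    At every arc position the meridional curvature is solved (Brent
    bracketing) so that the flow-rule velocity matches v_tip cos(phi); the
    dome ends where the wall drops below yield with phi -> pi/2, and the
    profile continues as a cylinder out to ``s_max``.
    """
    p = params
    k0 = _tip_curvature_steady(gradient, p)

    def kappa_at(s: float, phi: float, r: float) -> float:
        delta = evaluate_gradient(gradient, s)
        kt = np.sin(phi) / r
        sig_s = p.P / (2.0 * delta * kt)
        target = p.v_tip * np.cos(phi)

        def g(k: float) -> float:
            sig_t = p.P * (2.0 * kt - k) / (2.0 * delta * kt**2)
            sig_e = np.sqrt(sig_s**2 + sig_t**2 - 2.0 * p.nu * sig_s * sig_t)
            if sig_e <= p.sigma_y:
                flow = 0.0
            else:
                flow = (
                    p.Phi * (sig_e - p.sigma_y) * (sig_t - p.nu * sig_s) / (sig_e * kt)
                )
            return flow - target

        lo, hi = -5.0, 2.0 * kt + 20.0
        if g(lo) < 0 or g(hi) > 0:
            raise StalledGrowthError("self-similar dome cannot be continued")
        return float(brentq(g, lo, hi, xtol=1e-10))

    h = spacing / 5.0
    # series start: over the first spacing the curvature is ~ constant k0
    s_list = [0.0, spacing]
    phi_list = [0.0, k0 * spacing]
    r_list = [0.0, spacing - k0**2 * spacing**3 / 6.0]
    x_list = [0.0, -k0 * spacing**2 / 2.0]
    k_list = [k0, k0]
    s, phi, r, x = spacing, phi_list[1], r_list[1], x_list[1]
    phi_stop = np.pi / 2.0 - 5e-3
    while s < s_max - 1e-9 and phi < phi_stop:
        for _ in range(5):  # RK4 substeps between output points
            try:
                k1 = kappa_at(s, phi, r)
                p1 = (k1, np.cos(phi), -np.sin(phi))
                k2 = kappa_at(s + h / 2, phi + h / 2 * p1[0], r + h / 2 * p1[1])
                p2 = (k2, np.cos(phi + h / 2 * p1[0]), -np.sin(phi + h / 2 * p1[0]))
                k3 = kappa_at(s + h / 2, phi + h / 2 * p2[0], r + h / 2 * p2[1])
                p3 = (k3, np.cos(phi + h / 2 * p2[0]), -np.sin(phi + h / 2 * p2[0]))
                k4 = kappa_at(s + h, phi + h * p3[0], r + h * p3[1])
                p4 = (k4, np.cos(phi + h * p3[0]), -np.sin(phi + h * p3[0]))
            except StalledGrowthError:
                phi = phi_stop  # dome exhausted: finish as a cylinder
                break
            phi += h / 6.0 * (p1[0] + 2 * p2[0] + 2 * p3[0] + p4[0])
            r += h / 6.0 * (p1[1] + 2 * p2[1] + 2 * p3[1] + p4[1])
            x += h / 6.0 * (p1[2] + 2 * p2[2] + 2 * p3[2] + p4[2])
            s += h
            if phi >= phi_stop:
                break
        else:
            s_list.append(s)
            phi_list.append(phi)
            r_list.append(r)
            x_list.append(x)
            k_list.append(kappa_at(s, phi, r))
            continue
        break
    if phi >= phi_stop:
        # the dome closed: continue as an analytic cylinder
        R = r_list[-1]
        s_end = s_list[-1]
        n_add = int(np.ceil((s_max - s_end) / spacing))
        for i in range(1, n_add + 1):
            s_list.append(s_end + i * spacing)
            phi_list.append(np.pi / 2.0)
            r_list.append(R)
            x_list.append(x_list[len(s_list) - 2] - spacing)
            k_list.append(0.0)
    # resample onto a strictly uniform grid (the dome/cylinder junction may
    # land off-grid)
    x_u, r_u = resample_curve(np.asarray(x_list), np.asarray(r_list), spacing)
    return geometry_from_points(x_u, r_u, spacing)
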