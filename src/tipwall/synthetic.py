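"""Synthetic datasets with known ground truth for every pipeline input.

Each generator emulates one experimental data stream of the tip-growth
study — traced contours, TEM thickness tables, plasmolysis counts, bead
tracks, FRAP traces — around explicit true parameters, and returns the
truth alongside the data so recovery can be asserted.  Default truth
values are the point estimates of the studied *Ectocarpus* apical cells
(shank radius 3.27 µm, Pearson thickness gradient 36.2 nm / 591 nm /
16.81 µm, limit plasmolysis 1980 mOsm L⁻¹, shrink ratio 0.658, turgor
0.495 MPa, tip speed 2.5 µm h⁻¹).

All randomness flows from the mandatory ``seed`` of the SynthesisSpec;
identical spec and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .contours import RawContour, reconstruct_profile
from .microscopy import BeadTrack, FrapTrace
from .profile import MeridionalProfile, extend_with_cylinder
from .thickness import WallGradient

__all__ = [
    "SynthesisSpec",
    "ContourSpec",
    "ThicknessSpec",
    "PlasmolysisSpec",
    "BeadSpec",
    "FrapSpec",
    "cap_blend_profile",
    "make_contours",
    "make_thickness",
    "make_plasmolysis",
    "make_shrink_volumes",
    "make_beads",
    "make_frap",
    "make_variants",
    "auxin_plasmolysis_spec",
    "DEFAULT_SHRINK",
    "AUXIN_TURGOR",
    "AUXIN_GROWTH_FACTOR",
]

DEFAULT_SHRINK = 0.658  # V_plasmo / V_normal reproducing P = 0.495 MPa
AUXIN_TURGOR = 0.186  # MPa, measured under 1 µM IAA
AUXIN_GROWTH_FACTOR = 2.0  # tip-speed increase under 1 µM IAA


def _default_gradient() -> WallGradient:
    return WallGradient("pearson", 0.0362, 0.591, 16.81)


@dataclass(frozen=True)
class ContourSpec:
    tip_curvature: float = 0.27  # µm⁻¹, spherical-cap curvature of the dome
    shank_radius: float = 3.27  # µm
    half_length: float = 15.0  # µm of meridian traced on each side of the tip
    jitter_sd: float = 0.05  # µm, tracing noise normal to the wall
    trace_step: float = 0.2  # µm between hand-traced points
    n_cells: int = 17
    blend_width: float = 5.0  # µm over which the cap blends into the cylinder


@dataclass(frozen=True)
class ThicknessSpec:
    gradient: WallGradient = field(default_factory=_default_gradient)
    R: float = 3.27  # µm
    n_points: int = 2500
    n_cells: int = 15
    s_range: float = 70.0  # µm, measurements span ±s_range
    offset_sd: float = 0.8  # µm, sd of the per-cell section offset from the meridian
    noise_sd: float = 0.08  # lognormal sigma of multiplicative thickness noise
    cell_sd: float = 0.04  # lognormal sigma of the per-cell wall-thickness
    # scale (cells genuinely differ in overall wall thickness; this shared
    # factor is what correlates delta_min and delta_max across bootstrap
    # resamples)


@dataclass(frozen=True)
class PlasmolysisSpec:
    c_pl: float = 1980.0  # mOsm L⁻¹, true limit-plasmolysis osmolarity
    width: float = 150.0  # mOsm L⁻¹, logistic response width
    osmolarities: tuple[float, ...] = tuple(np.linspace(1400.0, 2600.0, 10))
    n_per_point: int = 150
    n_experiments: int = 3
    shrink: float = DEFAULT_SHRINK
    n_volume_cells: int = 9
    volume_cv: float = 0.04


@dataclass(frozen=True)
class BeadSpec:
    v_tip: float = 2.5 / 60.0  # µm min⁻¹
    n_beads: int = 20
    n_frames: int = 10
    frame_interval: float = 45.0  # min; beads only move while inside the
    # dome (the shank wall is static), so frames must be dense enough to
    # catch several displacements before a bead exits onto the shank
    angle_noise_sd: float = 0.52  # rad, matches the measured angular spread
    s0_min: float = 0.5  # µm, beads start within the dome
    s0_max: float = 4.0


@dataclass(frozen=True)
class FrapSpec:
    # per-zone recovery times; the minimum (fastest recovery) sits in zone C,
    # at the base of the dome, the configured exocytosis maximum.  All taus
    # are kept well inside the 50 s recovery window so they stay
    # identifiable at the assay's noise level.
    taus: tuple[tuple[str, float], ...] = (
        ("A", 26.0), ("B", 20.0), ("C", 12.0), ("D", 18.0), ("E", 15.0),
    )
    alpha: float = 100.0  # recovery amplitude, a.u.
    baseline: float = 5.0  # post-bleach residual signal, a.u.
    prebleach: float = 150.0  # pre-bleach plateau, a.u.
    background: float = 50.0  # a.u.
    background_drift: float = 0.1  # a.u. s⁻¹
    unbleached: float = 200.0  # a.u.
    decay_rate: float = 0.004  # s⁻¹, spontaneous photobleaching
    noise_sd: float = 10.0  # a.u. (alpha / noise_sd = SNR 10)
    n_traces: int = 9
    n_prebleach: int = 6
    n_recovery: int = 50


@dataclass(frozen=True)
class SynthesisSpec:
    seed: int
    contour: ContourSpec = field(default_factory=ContourSpec)
    thickness: ThicknessSpec = field(default_factory=ThicknessSpec)
    plasmolysis: PlasmolysisSpec = field(default_factory=PlasmolysisSpec)
    beads: BeadSpec = field(default_factory=BeadSpec)
    frap: FrapSpec = field(default_factory=FrapSpec)


def _rng(spec: SynthesisSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), stream])


def auxin_plasmolysis_spec(base: PlasmolysisSpec | None = None) -> PlasmolysisSpec:
    """Plasmolysis truth under auxin: the c_pl consistent with P = 0.186 MPa."""
    base = base or PlasmolysisSpec()
    c_pl = (410.0 * AUXIN_TURGOR + 1100.0) / base.shrink
    lo, hi = c_pl - 4 * base.width, c_pl + 4 * base.width
    osm = tuple(np.linspace(lo, hi, len(base.osmolarities)))
    return replace(base, c_pl=c_pl, osmolarities=osm)


# ---------------------------------------------------------------------------
# contours


def cap_blend_profile(
    tip_curvature: float = 0.27,
    shank_radius: float = 3.27,
    s_max: float = 40.0,
    spacing: float = 0.05,
    blend_width: float = 5.0,
) -> MeridionalProfile:
    """Dome of constant tip curvature blended smoothly into a cylinder.

    The meridional curvature is the cap value up to s1, then tapers to
    zero over ``blend_width`` while a sin² bump adds the extra turning
    needed to reach phi = pi/2 exactly at the configured shank radius; the
    bump amplitude and s1 are solved from the two constraints (total turn
    pi/2, final radius ``shank_radius``).
    """
    k0, w = tip_curvature, blend_width

    def kappa_fun(s1: float):
        amp = (np.pi / 2 - k0 * (s1 + w / 2)) * 2.0 / w

        def kappa(s):
            s = np.asarray(s, dtype=float)
            out = np.where(s <= s1, k0, 0.0)
            inside = (s > s1) & (s < s1 + w)
            u = (s[inside] - s1) / w
            out = out.astype(float)
            out[inside] = k0 * np.cos(np.pi * u / 2) ** 2 + amp * np.sin(np.pi * u) ** 2
            return out

        return kappa, amp

    def r_end(s1: float) -> float:
        kappa, _ = kappa_fun(s1)
        grid = np.linspace(0.0, s1 + w, 2001)
        phi = np.concatenate(
            [[0.0], np.cumsum((kappa(grid[1:]) + kappa(grid[:-1])) / 2 * np.diff(grid))]
        )
        return float(np.trapezoid(np.cos(phi), grid))

    s1_hi = np.pi / (2 * k0) - w / 2 - 1e-6  # amp >= 0 bound
    s1 = brentq(lambda s1: r_end(s1) - shank_radius, 0.05, s1_hi, xtol=1e-10)
    kappa, _ = kappa_fun(s1)
    dome_len = s1 + w
    grid = np.arange(0.0, dome_len + spacing, spacing / 2)
    profile = reconstruct_profile(grid, np.maximum(kappa(grid), 0.0), spacing=spacing)
    return extend_with_cylinder(profile, s_max)


def _two_sided_points(
    profile: MeridionalProfile, half_length: float, step: float
) -> tuple[np.ndarray, int]:
    """Full traced contour (u, v) from shank to shank; returns (points, tip index)."""
    m = profile.s <= half_length + 1e-9
    x, r = profile.x[m], profile.r[m]
    idx = np.arange(0, len(x), max(int(round(step / profile.spacing)), 1))
    if idx[-1] != len(x) - 1:
        idx = np.append(idx, len(x) - 1)
    xs, rs = x[idx], r[idx]
    pts = np.vstack(
        [np.column_stack([xs[::-1], -rs[::-1]]), np.column_stack([xs[1:], rs[1:]])]
    )
    return pts, len(xs) - 1


def _contour_normals(pts: np.ndarray) -> np.ndarray:
    tang = np.gradient(pts, axis=0)
    tang /= np.hypot(tang[:, 0], tang[:, 1])[:, None]
    return np.column_stack([tang[:, 1], -tang[:, 0]])


def make_contours(
    spec: SynthesisSpec,
    truth: MeridionalProfile | None = None,
) -> tuple[list[RawContour], MeridionalProfile]:
    """Jittered hand-traced contours around a known truth profile.

    The default truth dome is the cap-blend shape of the ContourSpec; pass
    ``truth`` (e.g. a steady self-similar profile) to trace around another
    shape instead.
    """
    c = spec.contour
    rng = _rng(spec, 1)
    if truth is None:
        truth = cap_blend_profile(
            c.tip_curvature, c.shank_radius,
            s_max=max(40.0, c.half_length + 5.0),
            blend_width=c.blend_width,
        )
    pts, _ = _two_sided_points(truth, c.half_length, c.trace_step)
    normals = _contour_normals(pts)
    contours = []
    for i in range(c.n_cells):
        noise = rng.normal(0.0, c.jitter_sd, size=len(pts))
        contours.append(RawContour(f"cell{i:02d}", pts + noise[:, None] * normals))
    return contours, truth


# ---------------------------------------------------------------------------
# thickness


def make_thickness(spec: SynthesisSpec) -> tuple[pd.DataFrame, WallGradient]:
    """Apparent TEM thickness with oblique-section bias and noise.

    Each synthetic cell is sectioned at one offset ``d`` from the meridian
    plane (|N(0, offset_sd)|, truncated to keep the section inside the
    wall); the apparent inner radius and width follow the exact
    circle-chord geometry, so the section correction inverts the bias
    exactly up to the multiplicative lognormal measurement noise.
    """
    t = spec.thickness
    rng = _rng(spec, 2)
    g = t.gradient
    d_cap = 0.95 * (t.R - g.delta_max)
    n_each = np.full(t.n_cells, t.n_points // t.n_cells)
    n_each[: t.n_points % t.n_cells] += 1
    rows = []
    for cell in range(t.n_cells):
        d = min(abs(rng.normal(0.0, t.offset_sd)), d_cap)
        s = rng.uniform(-t.s_range, t.s_range, size=n_each[cell])
        delta = g(np.abs(s)) * rng.lognormal(0.0, t.cell_sd)
        outer = np.sqrt(t.R**2 - d**2)
        a = np.sqrt((t.R - delta) ** 2 - d**2)
        w = (outer - a) * rng.lognormal(0.0, t.noise_sd, size=len(s))
        w = np.minimum(w, outer - a + (t.R - outer))  # keep a + w <= R
        rows.append(
            pd.DataFrame(
                {"cell_id": f"tem{cell:02d}", "s_um": s, "w_um": w, "a_um": a}
            )
        )
    return pd.concat(rows, ignore_index=True), g


# ---------------------------------------------------------------------------
# plasmolysis


def make_plasmolysis(spec: SynthesisSpec) -> tuple[pd.DataFrame, float]:
    """Binomial plasmolysis counts with a logistic response around c_pl."""
    p = spec.plasmolysis
    rng = _rng(spec, 3)
    rows = []
    for e in range(p.n_experiments):
        for c_e in p.osmolarities:
            if p.width == 0:
                prob = float(c_e >= p.c_pl)
            else:
                prob = 1.0 / (1.0 + np.exp(-(c_e - p.c_pl) / p.width))
            rows.append(
                {
                    "experiment_id": f"exp{e + 1}",
                    "c_e": c_e,
                    "n_total": p.n_per_point,
                    "n_plasmolyzed": int(rng.binomial(p.n_per_point, prob)),
                }
            )
    return pd.DataFrame(rows), p.c_pl


def make_shrink_volumes(spec: SynthesisSpec) -> tuple[np.ndarray, float]:
    """(V_plasmo, V_normal) pairs around the true shrink ratio."""
    p = spec.plasmolysis
    rng = _rng(spec, 4)
    v_norm = rng.lognormal(np.log(500.0), 0.2, size=p.n_volume_cells)  # µm³
    ratio = p.shrink * rng.lognormal(0.0, p.volume_cv, size=p.n_volume_cells)
    return np.column_stack([v_norm * ratio, v_norm]), p.shrink


# ---------------------------------------------------------------------------
# bead tracks


def make_beads(
    spec: SynthesisSpec,
) -> tuple[list[BeadTrack], list[np.ndarray], list[int], float]:
    """Beads advected by orthogonal self-similar growth, plus the contours.

    In the frame of the translating tip a surface-bound bead slides
    backwards along the meridian at ds/dt = v sin(phi(s)); its lab
    position is the tip-frame surface point plus the axial translation.
    Angular noise rotates each observed inter-frame displacement, so the
    true crossing angle is pi/2 with the configured angular spread.

    Returns (tracks, contour point arrays, tip indices, true angle).
    """
    b = spec.beads
    c = spec.contour
    rng = _rng(spec, 5)
    truth = cap_blend_profile(
        c.tip_curvature, c.shank_radius,
        s_max=max(40.0, c.half_length + b.v_tip * b.frame_interval * b.n_frames + 5.0),
        blend_width=c.blend_width,
    )
    phi_of_s = lambda s: np.interp(s, truth.s, truth.phi)
    times = b.frame_interval * np.arange(b.n_frames)
    contours, tips = [], []
    for t in times:
        pts, tip = _two_sided_points(
            truth.translated(b.v_tip * t), c.half_length, c.trace_step
        )
        contours.append(pts)
        tips.append(tip)
    tracks = []
    for i in range(b.n_beads):
        s = rng.uniform(b.s0_min, b.s0_max)
        side = 1.0 if rng.random() < 0.5 else -1.0
        exact = []
        t_cur = 0.0
        for t in times:
            # integrate ds/dt = v sin(phi) between observations
            while t_cur < t - 1e-9:
                h = min(1.0, t - t_cur)
                k1 = b.v_tip * np.sin(phi_of_s(s))
                k2 = b.v_tip * np.sin(phi_of_s(s + h * k1))
                s += h * (k1 + k2) / 2.0
                t_cur += h
            x = np.interp(s, truth.s, truth.x) + b.v_tip * t
            r = np.interp(s, truth.s, truth.r)
            exact.append([x, side * r])
        exact = np.asarray(exact)
        # a bead that has exited the dome onto the static shank stops
        # moving; truncate its track at the last real displacement
        moving = np.hypot(*np.diff(exact, axis=0).T) > 1e-3
        last = int(np.nonzero(moving)[0][-1]) + 1 if moving.any() else 0
        if last < 1:
            continue
        exact = exact[: last + 1]
        observed = [exact[0]]
        for k in range(1, len(exact)):
            d = exact[k] - exact[k - 1]
            eps = rng.normal(0.0, b.angle_noise_sd)
            rot = np.array(
                [[np.cos(eps), -np.sin(eps)], [np.sin(eps), np.cos(eps)]]
            )
            observed.append(observed[-1] + rot @ d)
        tracks.append(
            BeadTrack(f"bead{i:02d}", times[: last + 1], np.asarray(observed))
        )
    return tracks, contours, tips, np.pi / 2.0


# ---------------------------------------------------------------------------
# FRAP


def make_frap(spec: SynthesisSpec) -> tuple[list[FrapTrace], dict[str, dict]]:
    """Exponential FRAP recoveries with background, drift and decay."""
    f = spec.frap
    rng = _rng(spec, 6)
    t = np.concatenate(
        [np.arange(-f.n_prebleach, 0.0), np.arange(0.0, f.n_recovery + 1.0)]
    )
    decay = np.exp(-f.decay_rate * (t - t[0]))
    truth: dict[str, dict] = {}
    traces = []
    for zone, tau in f.taus:
        truth[zone] = {"alpha": f.alpha, "tau": tau}
        for _ in range(f.n_traces):
            Z = f.background + f.background_drift * (t - t[0])
            Z = Z + rng.normal(0.0, f.noise_sd / 4.0, size=len(t))
            U = f.unbleached * decay + Z + rng.normal(0.0, f.noise_sd, size=len(t))
            signal = np.where(
                t < 0,
                f.prebleach,
                f.baseline
                + (f.alpha * (1.0 - np.exp(-np.maximum(t, 0.0) / tau)) if tau > 0 else 0.0),
            )
            raw = signal * decay + Z + rng.normal(0.0, f.noise_sd, size=len(t))
            traces.append(FrapTrace(zone, t.copy(), raw, Z, U))
    return traces, truth


# ---------------------------------------------------------------------------
# the pollen-tube contrast configuration


def pollen_tube_config():
    """Geometry and parameters of the constant-thickness pollen-tube case.

    Tobacco pollen tube: shank radius ≈ 3.9 µm with a flat-tipped dome
    (apex curvature well below 1/R), a uniform 0.25 µm wall, turgor
    0.2 MPa and tip speed 540 µm h⁻¹.  Returns (profile, gradient,
    params).  With a uniform wall the stress decreases toward the tip
    while the strain rate peaks there, so the stress-strain relation is
    not a single Lockhart line — the contrast case to the thickness-
    gradient strategy.
    """
    from .mechanics import ViscoplasticParams

    profile = cap_blend_profile(
        tip_curvature=0.15, shank_radius=3.9, s_max=30.0, blend_width=3.0
    )
    gradient = WallGradient("pearson", 0.25 * (1 - 1e-6), 0.25, 1000.0)
    params = ViscoplasticParams(P=0.2, v_tip=540.0 / 60.0, sigma_y=0.0)
    return profile, gradient, params


# ---------------------------------------------------------------------------
# perturbation variants


def make_variants(
    obj: WallGradient | ContourSpec,
    kind: Literal["steep", "gentle", "flat", "sharp"],
    magnitude: float = 0.2,
):
    """Perturbed gradient (steep/gentle) or initial dome shape (flat/sharp).

    steep/gentle scale the gradient midpoint s_half by (1 -/+ magnitude);
    flat/sharp scale the dome tip curvature by (1 -/+ magnitude), the dome
    re-blending into the same shank radius.  magnitude 0 is the identity.
    """
    if kind in ("steep", "gentle"):
        if not isinstance(obj, WallGradient):
            raise TypeError("steep/gentle variants apply to a WallGradient")
        factor = 1.0 - magnitude if kind == "steep" else 1.0 + magnitude
        return replace(obj, s_half=obj.s_half * factor)
    if kind in ("flat", "sharp"):
        if not isinstance(obj, ContourSpec):
            raise TypeError("flat/sharp variants apply to a ContourSpec")
        factor = 1.0 - magnitude if kind == "flat" else 1.0 + magnitude
        return replace(obj, tip_curvature=obj.tip_curvature * factor)
    raise ValueError(f"unknown variant kind {kind!r}")
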