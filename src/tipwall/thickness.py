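"""Cell-wall thickness: oblique-section correction and gradient fitting.

Apparent wall thickness ``w`` measured on a longitudinal TEM section
overestimates the true thickness ``delta`` whenever the section plane
misses the meridian.  For a cylindrical cell of radius ``R`` sectioned at
offset ``d`` from the axis, the section shows the outer wall at apparent
half-width ``a + w = sqrt(R^2 - d^2)`` and the inner wall at
``a = sqrt((R - delta)^2 - d^2)``, which inverts exactly to

    delta = R - sqrt(a^2 + R^2 - (a + w)^2).

The corrected values follow an inverted-bell gradient delta(s) from a thin
tip to a thick shank, modelled by one of three sigmoid-in-s^2 families
(gauss / lorentz / pearson), each parameterized by delta_min (tip),
delta_max (asymptote) and the midpoint s_half.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_RADIUS = 3.27  # µm, shank radius used for the section correction

Family = Literal["gauss", "lorentz", "pearson"]

__all__ = [
    "DEFAULT_RADIUS",
    "ThicknessMeasurement",
    "WallGradient",
    "GeometryError",
    "GradientFitError",
    "correct_thickness",
    "evaluate_gradient",
    "fit_gradient",
    "read_thickness",
]


class GeometryError(ValueError):
    """Section geometry impossible (wider than the cell)."""


class GradientFitError(RuntimeError):
    """Nonlinear gradient fit failed to converge."""


@dataclass(frozen=True)
class ThicknessMeasurement:
    cell_id: str
    s: float  # signed meridional abscissa, µm
    w: float  # apparent thickness, µm
    a: float  # apparent inner radius, µm
    delta: float | None = None  # corrected thickness, µm


def correct_thickness(a, w, R: float = DEFAULT_RADIUS):
    """True wall thickness from the apparent section geometry (vectorized).

    delta = R - sqrt(a^2 + R^2 - (a + w)^2); the correction can only
    reduce the apparent value (delta <= w), with equality for a meridional
    section (a = R - w).
    """
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0) or np.any(a < 0):
        raise GeometryError("need w > 0 and a >= 0")
    if np.any(a + w > R * (1 + 1e-6)):
        raise GeometryError("section wider than the cell: a + w > R")
    rad = a**2 + R**2 - np.minimum(a + w, R) ** 2
    if np.any(rad < 0):
        raise GeometryError("negative radicand: inconsistent section geometry")
    delta = R - np.sqrt(rad)
    return float(delta) if delta.ndim == 0 else delta


def _gauss(s, dmin, dmax, s_half):
    return dmax - (dmax - dmin) * np.exp(-((s / s_half) ** 2) * np.log(2.0))


def _lorentz(s, dmin, dmax, s_half):
    return dmax - (dmax - dmin) / (1.0 + (s / s_half) ** 2)


def _pearson(s, dmin, dmax, s_half):
    return dmax - (dmax - dmin) / np.sqrt(1.0 + 3.0 * (s / s_half) ** 2)


_FAMILIES = {"gauss": _gauss, "lorentz": _lorentz, "pearson": _pearson}


@dataclass(frozen=True)
class WallGradient:
    """Fitted delta(s) model; all three families share delta at 0, inf, s_half."""

    family: Family
    delta_min: float  # µm, thickness at the tip
    delta_max: float  # µm, asymptotic shank thickness
    s_half: float  # µm, abscissa of the gradient midpoint
    rse: float = float("nan")  # residual standard error of the fit, µm

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown gradient family {self.family!r}")
        if not (0 < self.delta_min < self.delta_max):
            raise ValueError("need 0 < delta_min < delta_max")
        if self.s_half <= 0:
            raise ValueError("s_half must be positive")

    def __call__(self, s):
        return evaluate_gradient(self, s)

    def derivative(self, s):
        """d delta / ds, analytic, folded to |s|."""
        s = np.abs(np.asarray(s, dtype=float))
        d = self.delta_max - self.delta_min
        u = s / self.s_half
        if self.family == "gauss":
            return d * np.log(2.0) * 2 * s / self.s_half**2 * np.exp(-(u**2) * np.log(2.0))
        if self.family == "lorentz":
            return d * 2 * s / self.s_half**2 / (1.0 + u**2) ** 2
        return d * 3.0 * s / self.s_half**2 * (1.0 + 3.0 * u**2) ** -1.5


def evaluate_gradient(gradient: WallGradient, s):
    """delta(s) in µm; signed abscissae are folded to |s|."""
    s = np.abs(np.asarray(s, dtype=float))
    out = _FAMILIES[gradient.family](s, gradient.delta_min, gradient.delta_max, gradient.s_half)
    return float(out) if out.ndim == 0 else out


def read_thickness(path: str | Path, R: float = DEFAULT_RADIUS) -> pd.DataFrame:
    """Read a thickness table (cell_id, s_um, w_um[, a_um]) and correct it.

    When the apparent inner radius ``a`` is absent the section is assumed
    meridional (a = R - w), in which case the correction is the identity.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"cell_id", "s_um", "w_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "a_um" not in df.columns:
        df["a_um"] = R - df["w_um"]
    df["delta_um"] = correct_thickness(df["a_um"].to_numpy(), df["w_um"].to_numpy(), R)
    return df


def fit_gradient(
    s: Iterable[float],
    delta: Iterable[float],
    family: Family = "pearson",
    n_restarts: int = 5,
    seed: int = 0,
) -> WallGradient:
    """Nonlinear least-squares fit of (delta_min, delta_max, s_half).

    ``s`` is folded to |s| (the model is symmetric about the tip).  The fit
    is initialized from the data extremes and the median |s| and restarted
    from jittered starts if it fails; ``rse = sqrt(SSR / (n - 3))`` in µm.
    """
    s = np.abs(np.asarray(list(s), dtype=float))
    delta = np.asarray(list(delta), dtype=float)
    if len(s) < 10:
        raise GradientFitError("need at least 10 measurements")
    fun = _FAMILIES[family]
    p0 = np.array([max(delta.min(), 1e-4), delta.max(), np.median(s) or 1.0])
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for trial in range(n_restarts):
        start = p0 if trial == 0 else p0 * rng.lognormal(0.0, 0.3, size=3)
        try:
            popt, _ = curve_fit(
                fun, s, delta, p0=start,
                bounds=([1e-6, 1e-6, 1e-3], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            ssr = float(np.sum((fun(s, *popt) - delta) ** 2))
            rse = np.sqrt(ssr / (len(s) - 3))
            return WallGradient(family, float(popt[0]), float(popt[1]), float(popt[2]), rse)
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    raise GradientFitError(
        f"gradient fit did not converge after {n_restarts} restarts: {last_err}"
    )
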