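"""Turgor pressure from incipient-plasmolysis assays.

The external osmolarity at which half of the apical cells plasmolyze
(``c_pl``, the limit-plasmolysis point) estimates the internal osmolarity
of the shrunken cell.  Because the elastic wall relaxes upon plasmolysis,
``c_pl`` is corrected by the volume-shrink ratio ``x = V_plasmo/V_normal``
to the osmolarity of the turgid cell, ``c_i = x * c_pl``, and the turgor is

    P = (c_i - c_sea) / 410   [MPa],

with seawater at ``c_sea = 1100`` mOsm L⁻¹ and 410 mOsm L⁻¹ per MPa the
van 't Hoff conversion at culture temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

SEAWATER_OSMOLARITY = 1100.0  # mOsm L⁻¹
MOSM_PER_MPA = 410.0

__all__ = [
    "SEAWATER_OSMOLARITY",
    "MOSM_PER_MPA",
    "TurgorEstimate",
    "PlasmolysisError",
    "read_plasmolysis",
    "limit_plasmolysis",
    "shrink_coefficient",
    "turgor_from_plasmolysis",
]


class PlasmolysisError(ValueError):
    """Plasmolysis fractions never straddle 50%: c_pl not identifiable."""


@dataclass(frozen=True)
class TurgorEstimate:
    c_pl: float  # mean limit-plasmolysis osmolarity, mOsm L⁻¹
    per_experiment: dict[str, float] = field(default_factory=dict)
    shrink: float = 1.0  # V_plasmo / V_normal
    c_sea: float = SEAWATER_OSMOLARITY

    @property
    def c_i(self) -> float:
        return self.shrink * self.c_pl

    @property
    def turgor_mpa(self) -> float:
        return turgor_from_plasmolysis(self.c_pl, self.shrink, self.c_sea)


def read_plasmolysis(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"experiment_id", "c_e", "n_total", "n_plasmolyzed"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def _cpl_logistic(c_e: np.ndarray, n_tot: np.ndarray, n_pla: np.ndarray) -> float:
    """50% crossing from a binomial logistic (logit-linear in c_e) fit."""
    endog = np.column_stack([n_pla, n_tot - n_pla])
    exog = sm.add_constant(c_e)
    fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    b0, b1 = fit.params
    if b1 <= 0:
        raise PlasmolysisError("plasmolysis fraction does not increase with c_e")
    return float(-b0 / b1)


def _cpl_interpolate(c_e: np.ndarray, frac: np.ndarray) -> float:
    """50% crossing by linear interpolation of the sorted response."""
    order = np.argsort(c_e)
    c_e, frac = c_e[order], frac[order]
    above = np.nonzero(frac >= 0.5)[0]
    below = np.nonzero(frac < 0.5)[0]
    if len(above) == 0 or len(below) == 0:
        raise PlasmolysisError("fractions never cross 50%")
    i = above[above > below[0]][0] if (above > below[0]).any() else above[0]
    j = i - 1
    if frac[i] == frac[j]:
        return float(c_e[i])
    t = (0.5 - frac[j]) / (frac[i] - frac[j])
    return float(c_e[j] + t * (c_e[i] - c_e[j]))


def limit_plasmolysis(
    table: pd.DataFrame, method: str = "logistic"
) -> tuple[float, dict[str, float]]:
    """Per-experiment and mean limit-plasmolysis osmolarity.

    ``method='logistic'`` fits a monotone binomial logistic response in
    c_e and evaluates it at 50%; ``method='interpolate'`` linearly
    interpolates the observed fractions (exact reproduction of a hand
    calculation).
    """
    per: dict[str, float] = {}
    for exp_id, grp in table.groupby("experiment_id", sort=False):
        c_e = grp["c_e"].to_numpy(dtype=float)
        n_tot = grp["n_total"].to_numpy(dtype=float)
        n_pla = grp["n_plasmolyzed"].to_numpy(dtype=float)
        if np.any(c_e <= 0) or np.any(n_pla > n_tot) or np.any(n_pla < 0):
            raise ValueError(f"experiment {exp_id!r}: invalid counts or osmolarity")
        frac = n_pla / n_tot
        if frac.min() >= 0.5 or frac.max() < 0.5:
            raise PlasmolysisError(
                f"experiment {exp_id!r}: fractions never straddle 50%"
            )
        if method == "logistic":
            per[str(exp_id)] = _cpl_logistic(c_e, n_tot, n_pla)
        elif method == "interpolate":
            per[str(exp_id)] = _cpl_interpolate(c_e, frac)
        else:
            raise ValueError(f"unknown method {method!r}")
    return float(np.mean(list(per.values()))), per


def shrink_coefficient(volume_pairs: Iterable[Sequence[float]]) -> float:
    """Mean per-cell ratio V_plasmo / V_normal."""
    pairs = np.asarray(list(volume_pairs), dtype=float)
    if pairs.size == 0:
        raise ValueError("no volume pairs given")
    if np.any(pairs <= 0):
        raise ValueError("volumes must be positive")
    return float(np.mean(pairs[:, 0] / pairs[:, 1]))


def turgor_from_plasmolysis(
    c_pl: float, shrink: float, c_sea: float = SEAWATER_OSMOLARITY
) -> float:
    """Turgor P = (shrink * c_pl - c_sea) / 410, in MPa."""
    if not 0 < shrink <= 1:
        raise ValueError("shrink ratio must be in (0, 1]")
    return (shrink * c_pl - c_sea) / MOSM_PER_MPA
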