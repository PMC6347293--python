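"""Bootstrap robustness of the constant-plasticity Lockhart inference.

Cells are the resampling unit: whole contours and whole per-cell thickness
series are drawn with replacement, the averaged contour and the thickness
gradient are recomputed for every replicate, and the Lockhart regression
of expected strain rate on effective stress is refitted.  The spread of
r² across replicates measures how robust the single-Lockhart-line result
is to sampling variation in cell shape and wall thickness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contours import RawContour, average_profile
from .mechanics import ViscoplasticParams, lockhart_fit, mechanical_state
from .thickness import Family, fit_gradient

log = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "bootstrap", "single_replicate"]


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame  # delta_min, delta_max, s_half, Phi, sigma_y, r2
    n_failed: int
    seed: int

    @property
    def mean_r2(self) -> float:
        return float(self.replicates["r2"].mean())

    @property
    def r2_p5(self) -> float:
        """5th percentile: 95% of replicates have r² at or above this value."""
        return float(np.quantile(self.replicates["r2"], 0.05))

    def summary(self) -> dict[str, float]:
        rep = self.replicates
        return {
            "n_replicates": float(len(rep)),
            "mean_r2": self.mean_r2,
            "r2_p5": self.r2_p5,
            "r2_min": float(rep["r2"].min()),
            "r2_max": float(rep["r2"].max()),
            "mean_delta_span_um": float((rep["delta_max"] - rep["delta_min"]).mean()),
            "corr_delta_min_max": float(rep["delta_min"].corr(rep["delta_max"])),
            "corr_phi_sigma_y": float(rep["Phi"].corr(rep["sigma_y"])),
        }


def single_replicate(
    contours: list[RawContour],
    thickness_cells: dict[str, pd.DataFrame],
    params: ViscoplasticParams,
    family: Family = "pearson",
    spacing: float = 0.05,
    window: float = 0.2,
    trim_tail: float = 0.5,
    curvature_smoothing: float = 0.5,
) -> dict[str, float]:
    """The point-estimate pipeline on one (possibly resampled) sample.

    The last ``trim_tail`` µm of the averaged curvature grid are dropped:
    only the contours reaching farthest contribute there, so the mean is
    noisy in a region the Lockhart analysis does not use.
    ``curvature_smoothing`` (µm) low-passes the pooled mean curvature
    before reconstruction: the windowed mean still carries sampling noise
    on the grid scale, while real curvature features are several µm wide,
    and the effective stress is sensitive enough to pointwise curvature
    that unfiltered noise would dominate the stress-strain scatter.
    """
    profile = average_profile(
        contours,
        spacing=spacing,
        window=window,
        trim_tail=trim_tail,
        curvature_smoothing=curvature_smoothing,
    )
    pooled = pd.concat(thickness_cells.values(), ignore_index=True)
    gradient = fit_gradient(pooled["s_um"], pooled["delta_um"], family=family)
    mech = mechanical_state(profile, gradient, params, mask_invalid=True)
    phi, sigma_y, r2 = lockhart_fit(mech.sigma_e, mech.eps_star)
    return {
        "delta_min": gradient.delta_min,
        "delta_max": gradient.delta_max,
        "s_half": gradient.s_half,
        "Phi": phi,
        "sigma_y": sigma_y,
        "r2": r2,
    }


def bootstrap(
    contours: list[RawContour],
    thickness_cells: dict[str, pd.DataFrame],
    params: ViscoplasticParams,
    n_rep: int = 3000,
    seed: int = 0,
    family: Family = "pearson",
    resample: bool = True,
) -> BootstrapResult:
    """Resample cells with replacement and refit the whole pipeline.

    ``thickness_cells`` maps cell id -> corrected measurement table with
    columns s_um and delta_um; per-cell series are drawn as whole cells,
    independently of the contour draw.  Each replicate derives its RNG
    stream from (seed, replicate index), so results are independent of
    evaluation order.  With ``resample=False`` and n_rep=1 the identity
    sample reproduces the point-estimate pipeline exactly.
    """
    if not contours or not thickness_cells:
        raise ValueError("need non-empty contour and thickness datasets")
    cell_ids = list(thickness_cells)
    rows = []
    n_failed = 0
    for rep in range(n_rep):
        if resample:
            rng = np.random.default_rng([seed, rep])
            c_idx = rng.integers(0, len(contours), size=len(contours))
            t_idx = rng.integers(0, len(cell_ids), size=len(cell_ids))
            sample_contours = [contours[i] for i in c_idx]
            sample_thick = {
                f"draw{k}": thickness_cells[cell_ids[i]] for k, i in enumerate(t_idx)
            }
        else:
            sample_contours = contours
            sample_thick = thickness_cells
        try:
            rows.append(
                single_replicate(sample_contours, sample_thick, params, family)
            )
        except Exception as err:  # replicate-level failure
            n_failed += 1
            log.warning("bootstrap replicate %d failed: %s", rep, err)
    if n_failed > max(1, n_rep // 100):
        raise RuntimeError(
            f"{n_failed}/{n_rep} bootstrap replicates failed; data unusable"
        )
    return BootstrapResult(pd.DataFrame(rows), n_failed, seed)
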