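"""Global gamma-index comparison of two dose grids.

The gamma index combines a dose-difference criterion (percent of the global
maximum of the reference) with a distance-to-agreement criterion: a
reference voxel passes when some nearby evaluated position agrees within
the combined tolerance (gamma <= 1).  Voxels below a low-dose cutoff
(fraction of the reference global maximum) are excluded.

Implementation: the evaluated grid is trilinearly subsampled (3x per axis
by default), the displacement search is capped at 3x the DTA, and offsets
are visited in order of increasing distance with early termination once no
voxel's gamma can improve.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["GammaCriteria", "GammaResult", "gamma_pass_rate"]


@dataclass(frozen=True)
class GammaCriteria:
    dd_percent: float = 3.0
    dta_mm: float = 3.0
    low_dose_cutoff: float = 0.10
    search_radius_factor: float = 3.0
    subsample: int = 3

    def __post_init__(self) -> None:
        if min(self.dd_percent, self.dta_mm, self.low_dose_cutoff) <= 0:
            raise ValueError("gamma criteria must be positive")


@dataclass(frozen=True)
class GammaResult:
    pass_rate: float        # percent of evaluated voxels with gamma <= 1
    evaluated_count: int    # voxels above the low-dose cutoff (and in mask)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pass_rate <= 100.0):
            raise ValueError("pass_rate must lie in [0, 100]")


def _upsample(grid: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(grid, dtype=float)
    axes = [np.arange((n - 1) * factor + 1, dtype=float) / factor for n in grid.shape]
    cx, cy, cz = np.meshgrid(*axes, indexing="ij")
    return map_coordinates(np.asarray(grid, dtype=float),
                           [cx.ravel(), cy.ravel(), cz.ravel()],
                           order=1, mode="nearest").reshape(cx.shape)


def gamma_pass_rate(reference: np.ndarray, evaluated: np.ndarray,
                    spacing, criteria: GammaCriteria = GammaCriteria(),
                    mask: np.ndarray | None = None) -> GammaResult:
    """Global gamma pass rate of ``evaluated`` against ``reference``.

    ``spacing`` is the common voxel spacing in mm (scalar or length-3).
    """
    ref = np.asarray(reference, dtype=float)
    ev = np.asarray(evaluated, dtype=float)
    if ref.shape != ev.shape or ref.ndim != 3:
        raise ValueError("reference and evaluated grids must be congruent 3-D grids")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    gmax = ref.max()
    if gmax <= 0:
        raise ValueError("reference grid has no positive dose")
    dd_abs = criteria.dd_percent / 100.0 * gmax
    sel = ref >= criteria.low_dose_cutoff * gmax
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    n_eval = int(sel.sum())
    if n_eval == 0:
        return GammaResult(100.0, 0)

    f = criteria.subsample
    fine = _upsample(ev, f)
    fine_spacing = spacing / f
    radius = criteria.search_radius_factor * criteria.dta_mm
    max_off = [int(np.floor(radius / s)) for s in fine_spacing]
    offsets = []
    for di, dj, dk in product(*(range(-m, m + 1) for m in max_off)):
        r2 = ((di * fine_spacing[0]) ** 2 + (dj * fine_spacing[1]) ** 2
              + (dk * fine_spacing[2]) ** 2)
        if r2 <= radius * radius:
            offsets.append((r2, di, dj, dk))
    offsets.sort(key=lambda t: t[0])

    pad = [m for m in max_off]
    finep = np.pad(fine, [(p, p) for p in pad], mode="constant",
                   constant_values=np.nan)
    ii, jj, kk = np.nonzero(sel)
    base = (ii * f + pad[0], jj * f + pad[1], kk * f + pad[2])
    refv = ref[sel]
    g2 = np.full(refv.shape, np.inf)
    dta2 = criteria.dta_mm ** 2
    for r2, di, dj, dk in offsets:
        geom = r2 / dta2
        if geom >= g2.max():
            break  # no voxel can improve further
        evv = finep[base[0] + di, base[1] + dj, base[2] + dk]
        cand = ((evv - refv) / dd_abs) ** 2 + geom
        np.fmin(g2, cand, out=g2)
    pass_rate = 100.0 * float(np.mean(g2 <= 1.0 + 1e-12))
    return GammaResult(pass_rate, n_eval)
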