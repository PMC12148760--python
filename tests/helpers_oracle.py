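"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the production code paths: curve metrics are
re-derived by exhaustive scanning of a finely resampled curve, and the
gamma index by dense enumeration of displacements with a standalone
interpolator.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def fine_scan_crossings(depths, dose, level, step=0.01):
    """All crossings of ``level`` on a 0.01 mm resampling of the curve."""
    zf = np.arange(depths[0], depths[-1] + step / 2, step)
    df = np.interp(zf, depths, dose)
    above = df >= level
    idx = np.nonzero(above[:-1] != above[1:])[0]
    return zf[idx] + step / 2


def fine_scan_range(curve, level):
    xs = fine_scan_crossings(curve.depths, curve.dose, 0.8 * level)
    return xs[-1]


def fine_scan_modwidth(curve, level):
    xs = fine_scan_crossings(curve.depths, curve.dose, 0.9 * level)
    return xs[-1] - xs[0]


def gamma_oracle(reference, evaluated, spacing, dd_percent, dta_mm,
                 cutoff=0.10, radius_factor=3.0, step_mm=0.6):
    """Exhaustive fine-grid gamma pass rate.

    Dense displacement search on a ``step_mm`` lattice with a standalone
    trilinear interpolator of the evaluated grid; positions outside the grid
    are not candidates.
    """
    ref = np.asarray(reference, dtype=float)
    ev = np.asarray(evaluated, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    gmax = ref.max()
    dd_abs = dd_percent / 100.0 * gmax
    axes = [np.arange(n) * s for n, s in zip(ref.shape, spacing)]
    interp = RegularGridInterpolator(axes, ev, bounds_error=False,
                                     fill_value=np.nan)
    sel = ref >= cutoff * gmax
    ii, jj, kk = np.nonzero(sel)
    pos = np.stack([axes[0][ii], axes[1][jj], axes[2][kk]], axis=-1)
    refv = ref[sel]
    radius = radius_factor * dta_mm
    m = int(np.floor(radius / step_mm))
    g2 = np.full(refv.shape, np.inf)
    for di, dj, dk in product(range(-m, m + 1), repeat=3):
        off = np.array([di, dj, dk]) * step_mm
        r2 = float(off @ off)
        if r2 > radius * radius:
            continue
        vals = interp(pos + off)
        cand = ((vals - refv) / dd_abs) ** 2 + r2 / dta_mm ** 2
        cand[np.isnan(vals)] = np.inf
        np.minimum(g2, cand, out=g2)
    return 100.0 * float(np.mean(g2 <= 1.0 + 1e-12))
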