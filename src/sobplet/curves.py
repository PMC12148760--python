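"""Analytic proton depth-dose and LET-depth curves in water.

This module provides the 1-D building blocks of the delivery model: pristine
Bragg curves from a power-law stopping model convolved with Gaussian range
straggling, a residual-range LET parametrization, depth shifting (range
pull-back), and the clinical SOBP metrics -- distal D80 range, D90-to-D90
modulation width, and plateau normalization.

Conventions
-----------
* Depths are millimetres of water, on a uniformly spaced grid (0.5 mm by
  default, the measurement spacing).
* Dose is relative and unitless; a *normalized* SOBP has plateau level 100.
* D80/D90/D98 levels are percentages of the plateau (normalization) level,
  not of the global maximum, so all metrics are invariant under rescaling.
* All threshold crossings are located by linear interpolation between
  samples; the most distal crossing defines distal metrics and the most
  proximal crossing defines proximal metrics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "DepthDoseCurve",
    "LetDepthCurve",
    "PristinePeak",
    "SobpRequest",
    "pristine_bragg",
    "pristine_let",
    "shift_curve",
    "measure_range",
    "measure_modwidth",
    "measure_modwidth_d98",
    "normalize_sobp",
    "default_straggle",
    "read_curve_csv",
    "write_curve_csv",
]

DEFAULT_SPACING_MM = 0.5

# LET(residual range) model constants: LET ~ LET_COEFF * rr_cm**(-LET_EXPONENT),
# clipped to [LET_FLOOR, LET_CAP] keV/um. The power law follows from the
# range-energy relation R ~ alpha E^p with p ~ 1.77.
LET_COEFF = 2.0
LET_EXPONENT = 0.435
LET_CAP = 15.0
LET_FLOOR = 0.3


def _check_grid(depths: np.ndarray) -> float:
    depths = np.asarray(depths, dtype=float)
    if depths.ndim != 1 or depths.size < 2:
        raise ValueError("depth grid must be 1-D with at least two samples")
    diffs = np.diff(depths)
    if np.any(diffs <= 0):
        raise ValueError("depths must be strictly increasing")
    spacing = float(diffs[0])
    if not np.allclose(diffs, spacing, rtol=1e-6, atol=1e-9):
        raise ValueError("depths must be uniformly spaced")
    return spacing


@dataclass(frozen=True)
class DepthDoseCurve:
    """Relative dose versus depth in water on a uniform grid."""

    depths: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        _check_grid(depths)
        if dose.shape != depths.shape:
            raise ValueError("dose and depths must have equal length")
        if not np.all(np.isfinite(dose)):
            raise ValueError("dose must be finite")
        if np.any(dose < 0):
            raise ValueError("dose must be non-negative")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "dose", dose)

    @property
    def values(self) -> np.ndarray:
        return self.dose

    @property
    def spacing(self) -> float:
        return float(self.depths[1] - self.depths[0])

    def scaled(self, factor: float) -> "DepthDoseCurve":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return DepthDoseCurve(self.depths, self.dose * factor)


@dataclass(frozen=True)
class LetDepthCurve:
    """Dose-averaged LET (keV/um) versus depth in water on a uniform grid."""

    depths: np.ndarray
    let: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        let = np.asarray(self.let, dtype=float)
        _check_grid(depths)
        if let.shape != depths.shape:
            raise ValueError("let and depths must have equal length")
        if not np.all(np.isfinite(let)) or np.any(let < 0):
            raise ValueError("let must be finite and non-negative")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "let", let)

    @property
    def values(self) -> np.ndarray:
        return self.let

    @property
    def spacing(self) -> float:
        return float(self.depths[1] - self.depths[0])


@dataclass(frozen=True)
class PristinePeak:
    """Parameters of an analytic pristine Bragg peak.

    r80
        Distal 80%-of-maximum depth in mm of water (the clinical range of the
        pristine peak).
    sigma_straggle
        Gaussian range-straggling sigma in mm; sets the distal falloff width.
    fluence_loss_slope
        Exponential primary-fluence attenuation per mm (nuclear removal),
        lowering the peak-to-entrance ratio for deep peaks.
    """

    r80: float
    sigma_straggle: float
    fluence_loss_slope: float = 3e-4

    def __post_init__(self) -> None:
        if self.r80 <= 0:
            raise ValueError("r80 must be positive")
        if self.sigma_straggle <= 0:
            raise ValueError("sigma_straggle must be positive")
        if self.fluence_loss_slope < 0:
            raise ValueError("fluence_loss_slope must be non-negative")


@dataclass(frozen=True)
class SobpRequest:
    """Requested SOBP: range (distal D80) and modulation width, both cm."""

    range_cm: float
    modwidth_cm: float

    def __post_init__(self) -> None:
        if not (0 < self.modwidth_cm <= self.range_cm):
            raise ValueError("require 0 < modwidth_cm <= range_cm")

    @property
    def range_mm(self) -> float:
        return 10.0 * self.range_cm

    @property
    def modwidth_mm(self) -> float:
        return 10.0 * self.modwidth_cm


def default_straggle(r80_mm: float) -> float:
    """Default straggling sigma: distal 80-20 falloff of about 1% of range.

    A Gaussian-blurred edge falls from 80% to 20% over ~1.68 sigma, so
    sigma = 0.01 * r80 / 1.68.
    """
    return 0.01 * r80_mm / 1.68


# Bortfeld-style power-law for the unstraggled depth-dose term
#   a1*(R-z)^-p + a2*(R-z)^(1-p).
# The a2/a1 balance sets the entrance-to-peak ratio; a2 is kept low enough
# that wide-modulation SOBPs retain a proximal D90 shoulder.
_P_EXP = 0.435
_A1 = 17.93
_A2 = 0.30


@lru_cache(maxsize=256)
def _pristine_fine(r80: float, sigma: float, slope: float, zmax: float):
    """Pristine dose on a fine internal grid, distal D80 pinned to ``r80``.

    The unstraggled curve  a1*(R-z)^-0.435 + a2*(R-z)^0.565  is convolved
    with a Gaussian of width ``sigma``; the nominal range R is then iterated
    so the distal 80%-of-max depth of the blurred curve equals r80.
    """
    fine = 0.1
    pad = 6.0 * sigma + 10.0
    z = np.arange(0.0, zmax + pad, fine)

    def build(R_mm: float) -> np.ndarray:
        # cell-averaged power law: the (R-z)^-p term is integrable-singular
        # at z=R, so each fine cell takes the analytic mean of the
        # antiderivative rather than a point sample
        x_hi = np.maximum(R_mm - (z - fine / 2.0), 0.0) / 10.0
        x_lo = np.maximum(R_mm - (z + fine / 2.0), 0.0) / 10.0
        w_cm = fine / 10.0
        r_cm = R_mm / 10.0
        a1 = _A1 / (1.0 + 0.012 * r_cm)
        a2 = _A2 / (1.0 + 0.012 * r_cm)
        e1 = 1.0 - _P_EXP
        e2 = 2.0 - _P_EXP
        raw = (a1 * (x_hi ** e1 - x_lo ** e1) / e1
               + a2 * (x_hi ** e2 - x_lo ** e2) / e2) / w_cm
        raw *= np.exp(-slope * z)
        return gaussian_filter1d(raw, sigma / fine, mode="nearest", truncate=8.0)

    R = r80
    for _ in range(4):
        d = build(R)
        d80 = _distal_crossing(z, d, 0.8 * d.max())
        R += r80 - d80
    d = build(R)
    d *= 100.0 / d.max()
    return z, d


def _distal_crossing(depths: np.ndarray, vals: np.ndarray, level: float) -> float:
    xs = _crossings(depths, vals, level)
    if not xs:
        raise ValueError("no crossing of requested level: truncated or invalid curve")
    return xs[-1]


def _crossings(depths: np.ndarray, vals: np.ndarray, level: float) -> list[float]:
    """All depths where the sampled curve crosses ``level``, interpolated."""
    d = vals - level
    out: list[float] = []
    for i in range(len(d) - 1):
        a, b = d[i], d[i + 1]
        if a == 0.0:
            out.append(float(depths[i]))
        elif a * b < 0.0:
            t = a / (a - b)
            out.append(float(depths[i] + t * (depths[i + 1] - depths[i])))
    if d[-1] == 0.0:
        out.append(float(depths[-1]))
    return out


def _require_coverage(peak: PristinePeak, depths: np.ndarray) -> None:
    spacing = _check_grid(depths)
    tail = peak.r80 + 5.0 * peak.sigma_straggle
    if depths[0] > spacing + 1e-9 or depths[-1] < tail - 1e-9:
        raise ValueError(
            f"depth grid [{depths[0]:g}, {depths[-1]:g}] mm truncates the peak "
            f"(need coverage of [0, {tail:g}] mm)"
        )


def pristine_bragg(peak: PristinePeak, depths: np.ndarray) -> DepthDoseCurve:
    """Analytic pristine Bragg curve sampled on ``depths``.

    The returned curve is single-peaked with its distal 80%-of-maximum depth
    at ``peak.r80`` (within one grid step) and dose falling to zero beyond
    ``r80 + 5 sigma``.
    """
    depths = np.asarray(depths, dtype=float)
    _require_coverage(peak, depths)
    z, d = _pristine_fine(
        float(peak.r80), float(peak.sigma_straggle), float(peak.fluence_loss_slope),
        float(depths[-1]),
    )
    vals = np.interp(depths, z, d, left=d[0], right=0.0)
    return DepthDoseCurve(depths, vals)


def pristine_let(peak: PristinePeak, depths: np.ndarray) -> LetDepthCurve:
    """Track-end LET model: monotone rise with shrinking residual range.

    LET depends on depth only through the residual range r80 - z, so two
    peaks of different energy agree at equal residual range. Values are
    capped at LET_CAP (track end) and floored at LET_FLOOR.
    """
    depths = np.asarray(depths, dtype=float)
    _require_coverage(peak, depths)
    rr_cm = np.maximum(peak.r80 - depths, 0.0) / 10.0
    rr_min = (LET_COEFF / LET_CAP) ** (1.0 / LET_EXPONENT)
    rr_cm = np.maximum(rr_cm, rr_min)
    let = np.clip(LET_COEFF * rr_cm ** (-LET_EXPONENT), LET_FLOOR, LET_CAP)
    return LetDepthCurve(depths, let)


def shift_curve(curve, wet_pullback: float):
    """Translate a curve to shallower depth by ``wet_pullback`` mm.

    The shifted curve is resampled on the original grid; samples that would
    need data beyond either edge of the stored curve take the nearest edge
    value (the entrance value proximally, the tail value distally).
    """
    if wet_pullback < 0:
        raise ValueError("wet_pullback must be non-negative")
    vals = curve.values
    new = np.interp(curve.depths + wet_pullback, curve.depths, vals,
                    left=vals[0], right=vals[-1])
    return replace(curve, **{_value_field(curve): new})


def _value_field(curve) -> str:
    if isinstance(curve, DepthDoseCurve):
        return "dose"
    if isinstance(curve, LetDepthCurve):
        return "let"
    raise TypeError(f"unsupported curve type {type(curve)!r}")


def plateau_level(curve: DepthDoseCurve) -> float:
    """Estimate the plateau (normalization) level of a dose curve.

    Median of all samples within 10% of the maximum -- robust to plateau
    ripple and to a small distal crest, and scale-invariant. A normalized
    SOBP returns ~100.
    """
    m = float(np.max(curve.dose))
    if m <= 0:
        raise ValueError("curve has no positive dose")
    top = curve.dose[curve.dose >= 0.9 * m]
    return float(np.median(top))


def measure_range(curve: DepthDoseCurve, level: float | None = None) -> float:
    """Clinical range: most distal crossing of 80% of the plateau level."""
    lvl = plateau_level(curve) if level is None else float(level)
    xs = _crossings(curve.depths, curve.dose, 0.8 * lvl)
    if not xs:
        raise ValueError("no distal D80 crossing: truncated or invalid curve")
    return xs[-1]


def measure_modwidth(curve: DepthDoseCurve, level: float | None = None) -> float:
    """Modulation width: most distal minus most proximal D90 crossing."""
    lvl = plateau_level(curve) if level is None else float(level)
    xs = _crossings(curve.depths, curve.dose, 0.9 * lvl)
    if len(xs) < 2:
        raise ValueError("fewer than two D90 crossings: cannot measure modulation width")
    return xs[-1] - xs[0]


def measure_modwidth_d98(curve: DepthDoseCurve, level: float | None = None) -> float:
    """Alternative width restricted to the flat SOBP: proximal D98 to distal D90.

    Using a 98% proximal threshold excludes the slow proximal build-up that
    the D90-to-D90 definition sweeps up for large modulation widths.
    """
    lvl = plateau_level(curve) if level is None else float(level)
    prox = _crossings(curve.depths, curve.dose, 0.98 * lvl)
    dist = _crossings(curve.depths, curve.dose, 0.9 * lvl)
    if not prox or not dist:
        raise ValueError("missing D98/D90 crossings: cannot measure modulation width")
    return dist[-1] - prox[0]


def normalize_sobp(curve: DepthDoseCurve, request: SobpRequest) -> DepthDoseCurve:
    """Normalize to mean dose 100 in the centre of the SOBP +-25% of the
    requested modulation width.

    The SOBP centre is anchored to the well-determined distal edge:
    centre = (distal D90 depth) - 0.5 * requested modulation width.
    """
    lvl = plateau_level(curve)
    d90 = _distal_crossing(curve.depths, curve.dose, 0.9 * lvl)
    center = d90 - 0.5 * request.modwidth_mm
    lo = center - 0.25 * request.modwidth_mm
    hi = center + 0.25 * request.modwidth_mm
    if lo < curve.depths[0] - 1e-9 or hi > curve.depths[-1] + 1e-9:
        raise ValueError(
            f"normalization window [{lo:.2f}, {hi:.2f}] mm extends outside the depth grid"
        )
    sel = (curve.depths >= lo - 1e-9) & (curve.depths <= hi + 1e-9)
    mean = float(np.mean(curve.dose[sel]))
    if mean <= 0:
        raise ValueError("normalization window has non-positive mean dose")
    return DepthDoseCurve(curve.depths, curve.dose * (100.0 / mean))


# ---------------------------------------------------------------------------
# CSV interchange: two columns (depth_mm, value), header required, 6
# significant digits, bit-stable on round trip.

def write_curve_csv(curve, path) -> None:
    name = "dose" if isinstance(curve, DepthDoseCurve) else "let_kev_um"
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["depth_mm", name])
        for z, v in zip(curve.depths, curve.values):
            w.writerow([f"{z:.6g}", f"{v:.6g}"])
    tmp.replace(path)


def read_curve_csv(path):
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if len(header) != 2 or header[0] != "depth_mm":
            raise ValueError(f"unrecognized curve CSV header: {header!r}")
        rows = [(float(a), float(b)) for a, b in r]
    depths = np.array([a for a, _ in rows])
    vals = np.array([b for _, b in rows])
    if header[1] == "dose":
        return DepthDoseCurve(depths, vals)
    if header[1] == "let_kev_um":
        return LetDepthCurve(depths, vals)
    raise ValueError(f"unrecognized value column: {header[1]!r}")
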