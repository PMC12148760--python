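"""Zero-angle calibration of a modulation wheel against measured SOBPs.

The wheel's zero-angle (beam position at beam-on, inside the brass block) is
not known to the delivery model and is recovered by matching simulated to
measured SOBPs.  Each measurement records the requested range/modulation
width, the machine's rotation angle for that delivery, and the measured
depth-dose curve; the simulation replays the recorded rotation at candidate
zero-angles and scores the mean absolute modulation-width difference.

Two-stage search: a coarse 2-degree scan starting from 0 degrees, then a
grid search of +-3.5 degrees around the coarse minimum with 0.5-degree
spacing (15 candidates, ties broken toward the smallest angle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .curves import DepthDoseCurve, SobpRequest, measure_modwidth, measure_range, normalize_sobp
from .wheel import WheelSpec, replay_delivery, synthesize_sobp

__all__ = [
    "Measurement",
    "MeasurementSet",
    "ValidationRow",
    "coarse_search",
    "grid_search",
    "calibrate",
    "validate",
    "validation_frame",
    "RANGE_GOAL_MM",
    "MODWIDTH_GOAL_MM",
]

# delivery-QA accuracy goals
RANGE_GOAL_MM = 1.0
MODWIDTH_GOAL_MM = 2.0

COARSE_STEP_DEG = 2.0
GRID_HALF_WIDTH_DEG = 3.5
GRID_STEP_DEG = 0.5

# Pre-metric smoothing of depth-dose scans, mm.  Chamber scans are smoothed
# before threshold crossings are read off; the same filter is applied to
# simulated curves so any residual bias cancels in the differences.
METRIC_SMOOTHING_MM = 1.0


@dataclass(frozen=True)
class Measurement:
    request: SobpRequest
    rotation_angle: float  # machine rotation recorded for this delivery, deg
    curve: DepthDoseCurve


@dataclass(frozen=True)
class MeasurementSet:
    """Measured SOBPs for one wheel (typically 5 or 6 deliveries)."""

    entries: tuple

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        if not entries:
            raise ValueError("measurement set must not be empty")
        spacings = {round(m.curve.spacing, 6) for m in entries}
        if len(spacings) != 1:
            raise ValueError("all measurement curves must share one grid spacing")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class ValidationRow:
    request: SobpRequest
    range_diff: float      # simulated - measured, mm
    modwidth_diff: float   # simulated - measured, mm

    @property
    def pass_range(self) -> bool:
        return abs(self.range_diff) <= RANGE_GOAL_MM

    @property
    def pass_modwidth(self) -> bool:
        return abs(self.modwidth_diff) <= MODWIDTH_GOAL_MM


def _smooth(curve: DepthDoseCurve) -> DepthDoseCurve:
    sigma = METRIC_SMOOTHING_MM / curve.spacing
    return DepthDoseCurve(curve.depths,
                          gaussian_filter1d(curve.dose, sigma, mode="nearest"))


def _measured_metrics(meas: Measurement):
    curve = normalize_sobp(_smooth(meas.curve), meas.request)
    return measure_range(curve), measure_modwidth(curve)


def _simulated_curve(wheel: WheelSpec, zero_angle: float, meas: Measurement):
    proto = replay_delivery(wheel, zero_angle, meas.rotation_angle, meas.request)
    dose, _ = synthesize_sobp(wheel, proto, meas.request)
    return _smooth(dose)


def _objective(meas: MeasurementSet, wheel: WheelSpec, zero_angle: float) -> float:
    """Mean |modulation-width difference| over the measurement set.

    Range is reported in validation but not optimized: the delivered range
    is pinned by the beam energy, not the zero-angle.  Normalization happens
    before any metric, so the objective is invariant to curve rescaling.
    """
    total = 0.0
    for m in meas:
        try:
            sim = _simulated_curve(wheel, zero_angle, m)
            mw_sim = measure_modwidth(sim)
            _, mw_meas = _measured_metrics(m)
        except ValueError:
            return float("inf")
        total += abs(mw_sim - mw_meas)
    return total / len(meas)


def _argmin_smallest_angle(angles, values) -> float:
    order = np.argsort(angles, kind="stable")
    best_a, best_v = None, float("inf")
    for k in order:
        if values[k] < best_v:
            best_a, best_v = angles[k], values[k]
    if best_a is None or not np.isfinite(best_v):
        raise ValueError("calibration objective is non-finite for every candidate")
    return float(best_a)


def coarse_search(meas: MeasurementSet, wheel: WheelSpec,
                  step_deg: float = COARSE_STEP_DEG) -> float:
    """Coarse zero-angle scan over [0, 360) starting at 0 degrees."""
    angles = np.arange(0.0, 360.0, step_deg)
    values = [_objective(meas, wheel, a) for a in angles]
    return _argmin_smallest_angle(angles, values)


def grid_search(meas: MeasurementSet, wheel: WheelSpec, center: float) -> float:
    """Fine grid of 15 candidates: center +- {0, 0.5, ..., 3.5} degrees."""
    offsets = np.arange(-GRID_HALF_WIDTH_DEG, GRID_HALF_WIDTH_DEG + GRID_STEP_DEG / 2,
                        GRID_STEP_DEG)
    angles = (center + offsets) % 360.0
    values = [_objective(meas, wheel, a) for a in angles]
    return _argmin_smallest_angle(angles, values)


def calibrate(meas: MeasurementSet, wheel: WheelSpec) -> float:
    """Two-stage zero-angle recovery: coarse scan then fine grid."""
    return grid_search(meas, wheel, coarse_search(meas, wheel))


def validate(meas: MeasurementSet, wheel: WheelSpec, zero_angle: float):
    """Per-delivery range/modulation-width differences (simulated - measured)."""
    rows = []
    for m in meas:
        try:
            sim = _simulated_curve(wheel, zero_angle, m)
            r_sim = measure_range(sim)
            mw_sim = measure_modwidth(sim)
            r_meas, mw_meas = _measured_metrics(m)
        except ValueError as exc:
            raise ValueError(
                f"metric failure for R{m.request.range_cm:.2f}/"
                f"M{m.request.modwidth_cm:.2f}: {exc}"
            ) from exc
        rows.append(ValidationRow(m.request, r_sim - r_meas, mw_sim - mw_meas))
    return rows


def validation_frame(rows) -> pd.DataFrame:
    return pd.DataFrame({
        "request_range_cm": [r.request.range_cm for r in rows],
        "request_modwidth_cm": [r.request.modwidth_cm for r in rows],
        "range_diff_mm": [r.range_diff for r in rows],
        "modwidth_diff_mm": [r.modwidth_diff for r in rows],
        "pass_range": [r.pass_range for r in rows],
        "pass_modwidth": [r.pass_modwidth for r in rows],
    })
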