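"""Range-modulation-wheel model and SOBP synthesis.

A long-range modulation wheel is a rotating absorber built from three
stacked plates -- a low-Z (Lexan/carbon) upstream plate with stepped
thickness, a fixed 1 mm aluminium centre plate, and a stepped lead
downstream plate -- plus a brass block separating the thickest from the
thinnest step so the largest and smallest range pull-backs never overlap.
Each angular step pulls the pristine Bragg peak back by its water-equivalent
thickness (WET) relative to the thinnest step.

Delivery protocol: the beam turns on with the wheel at its *zero-angle*,
which sits inside the brass block (no dose), then the wheel rotates through
a *rotation angle* determined by the requested modulation width.  The
repeated rotate-and-return cycles of the hardware, together with beam
current modulation, are collapsed here into a single per-step dwell-weight
vector: each step's weight is its flat-SOBP current weight times the
fraction of the step's angular span actually swept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import nnls

from .curves import (
    DepthDoseCurve,
    LetDepthCurve,
    PristinePeak,
    SobpRequest,
    _pristine_fine,
    default_straggle,
    measure_modwidth,
    measure_range,
    normalize_sobp,
    pristine_let,
)

__all__ = [
    "BLOCKED",
    "WheelStep",
    "WheelSpec",
    "DeliveryProtocol",
    "wet_at_angle",
    "rotation_for_modwidth",
    "replay_delivery",
    "flatten_weights",
    "synthesize_sobp",
    "wheel_to_yaml",
    "wheel_from_yaml",
]

DEFAULT_RSP = {"lowz": 1.15, "aluminium": 2.1, "lead": 5.0}


class _Blocked:
    """Marker for beam positions inside the brass block (no transmission)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "BLOCKED"


BLOCKED = _Blocked()


@dataclass(frozen=True)
class WheelStep:
    angular_start: float
    angular_span: float
    upstream_mm: float
    downstream_mm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.angular_start < 360.0):
            raise ValueError("angular_start must lie in [0, 360)")
        if self.angular_span <= 0:
            raise ValueError("angular_span must be positive")
        if self.upstream_mm < 0 or self.downstream_mm < 0:
            raise ValueError("plate thicknesses must be non-negative")


@dataclass(frozen=True)
class WheelSpec:
    """Three-plate modulation wheel: stepped absorber plus brass block.

    ``steps`` must be listed in sweep order (the order the beam crosses them
    when rotating away from the brass block), with strictly increasing
    pull-back.
    """

    steps: tuple
    brass_start: float
    brass_span: float
    center_plate_mm: float = 1.0
    material_rsp: dict = field(default_factory=lambda: dict(DEFAULT_RSP))

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        if abs(self.center_plate_mm - 1.0) > 1e-9:
            raise ValueError("centre plate thickness is fixed at 1 mm")
        if self.brass_span <= 0 or self.brass_span >= 360:
            raise ValueError("brass_span must be in (0, 360)")
        for key in ("lowz", "aluminium", "lead"):
            if key not in self.material_rsp:
                raise ValueError(f"material_rsp missing {key!r}")
        self._check_tiling()
        self._check_monotone()

    def _check_tiling(self) -> None:
        ivals = [(self.brass_start % 360.0, self.brass_span)]
        ivals += [(s.angular_start, s.angular_span) for s in self.steps]
        total = sum(span for _, span in ivals)
        if abs(total - 360.0) > 1e-6:
            raise ValueError(f"step spans plus brass must tile 360 deg (got {total:g})")
        ivals.sort()
        for (s0, sp0), (s1, _) in zip(ivals, ivals[1:]):
            if abs((s0 + sp0) - s1) > 1e-6:
                raise ValueError("steps and brass block overlap or leave gaps")

    def _check_monotone(self) -> None:
        up = np.array([s.upstream_mm for s in self.steps])
        down = np.array([s.downstream_mm for s in self.steps])
        inc_dec = np.all(np.diff(up) > 0) and np.all(np.diff(down) < 0)
        dec_inc = np.all(np.diff(up) < 0) and np.all(np.diff(down) > 0)
        if not (inc_dec or dec_inc):
            raise ValueError(
                "upstream thickness must change monotonically across steps with "
                "the downstream plate complementing it"
            )
        if np.any(np.diff(self.pullbacks) <= 0):
            raise ValueError("pull-back must increase strictly in sweep order")

    @property
    def brass_end(self) -> float:
        return self.brass_start + self.brass_span

    @property
    def wets(self) -> np.ndarray:
        rsp = self.material_rsp
        return np.array([
            s.upstream_mm * rsp["lowz"]
            + self.center_plate_mm * rsp["aluminium"]
            + s.downstream_mm * rsp["lead"]
            for s in self.steps
        ])

    @property
    def pullbacks(self) -> np.ndarray:
        w = self.wets
        return w - w.min()

    @property
    def max_pullback(self) -> float:
        return float(self.pullbacks.max())

    def in_brass(self, angle: float) -> bool:
        a = (angle - self.brass_start) % 360.0
        return a < self.brass_span


@dataclass(frozen=True)
class DeliveryProtocol:
    """One beam-on pass: start angle, swept rotation, per-step dwell weights.

    For a hardware (vendor-side) delivery the zero-angle lies inside the
    brass block; calibration replays recorded rotations at arbitrary
    candidate zero-angles, so brass membership is checked by
    :func:`rotation_for_modwidth`, not here.
    """

    zero_angle: float
    rotation_angle: float
    step_weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.step_weights, dtype=float)
        if not (0.0 < self.rotation_angle < 360.0):
            raise ValueError("rotation_angle must lie in (0, 360)")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("step_weights must be finite and non-negative")
        object.__setattr__(self, "step_weights", w)


def wet_at_angle(wheel: WheelSpec, angle: float):
    """Water-equivalent thickness of the wheel at a beam angle, or BLOCKED.

    WET is piecewise constant: the sum over the three plates of physical
    thickness times material relative stopping power.
    """
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    a = float(angle) % 360.0
    if wheel.in_brass(a):
        return BLOCKED
    for s, w in zip(wheel.steps, wheel.wets):
        if (a - s.angular_start) % 360.0 < s.angular_span:
            return float(w)
    raise ValueError(f"angle {angle:g} deg not covered by any step")  # pragma: no cover


def _dwell_fractions(wheel: WheelSpec, zero_angle: float, rotation_angle: float) -> np.ndarray:
    """Fraction of each step's angular span covered by the sweep arc."""
    z = float(zero_angle) % 360.0
    rot = float(rotation_angle)
    out = np.zeros(len(wheel.steps))
    for i, s in enumerate(wheel.steps):
        start = z + (s.angular_start - z) % 360.0
        pieces = []
        if start + s.angular_span <= z + 360.0:
            pieces.append((start, start + s.angular_span))
        else:  # step straddles the arc origin
            pieces.append((start, z + 360.0))
            pieces.append((z, start + s.angular_span - 360.0))
        cov = sum(max(0.0, min(z + rot, b) - max(z, a)) for a, b in pieces)
        out[i] = cov / s.angular_span
    return out


def pristine_for_request(request: SobpRequest, r80_mm: float | None = None) -> PristinePeak:
    r80 = request.range_mm if r80_mm is None else r80_mm
    return PristinePeak(r80=r80, sigma_straggle=default_straggle(r80))


def _pristine_tables(peak: PristinePeak, zmax: float):
    z, d = _pristine_fine(float(peak.r80), float(peak.sigma_straggle),
                          float(peak.fluence_loss_slope), float(zmax))
    return z, d


def flatten_weights(pullbacks, pristine: PristinePeak, plateau_interval) -> np.ndarray:
    """Beam-current weights giving a flat SOBP over ``plateau_interval``.

    Non-negative least squares fit of the pulled-back pristine curves to a
    constant over the plateau samples. Duplicate pull-backs share their
    weight equally (symmetric tie). Weights are scaled so the largest is 1;
    the deepest (zero pull-back) component carries the largest weight.
    """
    p = np.asarray(pullbacks, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one pull-back")
    if p.size == 1:
        return np.array([1.0])
    lo, hi = float(plateau_interval[0]), float(plateau_interval[1])
    if not hi > lo:
        raise ValueError("plateau interval is empty or inverted")
    zs = np.linspace(lo, hi, max(7, int(round((hi - lo) / 0.5)) + 1))
    zf, df = _pristine_tables(pristine, hi + p.max() + 1.0)

    uniq, inv, counts = np.unique(np.round(p, 9), return_inverse=True,
                                  return_counts=True)
    A = np.empty((zs.size, uniq.size))
    for k, pk in enumerate(uniq):
        A[:, k] = np.interp(zs + pk, zf, df, left=df[0], right=0.0)
    w_uniq, _ = nnls(A, np.ones(zs.size))
    w = w_uniq[inv] / counts[inv]
    if w.max() <= 0:
        raise ValueError("flatness fit produced all-zero weights")
    return w / w.max()


def _plateau_interval(r80_mm: float, max_pullback: float):
    # from just distal of the shallowest component's peak to just proximal
    # of the distal falloff
    lo = r80_mm - max_pullback + 2.0
    hi = r80_mm - 3.0
    if hi - lo < 2.0:
        lo = r80_mm - max_pullback
        hi = r80_mm - 1.0
    return lo, hi


def replay_delivery(wheel: WheelSpec, zero_angle: float, rotation_angle: float,
                    request: SobpRequest) -> DeliveryProtocol:
    """Protocol for a recorded rotation replayed at an arbitrary zero-angle.

    Used by calibration: the rotation angle is machine delivery metadata,
    while the zero-angle is the model parameter under search.  Step weights
    are the flat-SOBP current weights of the swept step set times the dwell
    fraction of each step.
    """
    dwell = _dwell_fractions(wheel, zero_angle, rotation_angle)
    swept = np.flatnonzero(dwell > 1e-12)
    if swept.size == 0:
        return DeliveryProtocol(zero_angle % 360.0, rotation_angle, dwell)
    p = wheel.pullbacks[swept]
    pristine = pristine_for_request(request)
    flat = flatten_weights(p, pristine,
                           _plateau_interval(request.range_mm, max(p.max(), 4.0)))
    weights = np.zeros(len(wheel.steps))
    weights[swept] = flat * dwell[swept]
    return DeliveryProtocol(zero_angle % 360.0, rotation_angle, weights)


def rotation_for_modwidth(wheel: WheelSpec, zero_angle: float,
                          request: SobpRequest) -> DeliveryProtocol:
    """Vendor-side translation of a requested modulation width into a
    rotation angle starting at the (brass-block) zero-angle.

    The sweep crosses the remaining brass, then the steps in order of
    increasing pull-back until the accumulated pull-back covers the request;
    the dwell on the final step is refined so the synthesized D90-to-D90
    width matches the request.
    """
    z = float(zero_angle) % 360.0
    if not wheel.in_brass(z):
        raise ValueError("zero-angle must lie inside the brass block segment")
    m = request.modwidth_mm
    p = wheel.pullbacks
    if m > p[-1] + 2.0:
        raise ValueError(
            f"modulation width {m:.1f} mm unreachable; wheel maximum pull-back "
            f"is {p[-1]:.1f} mm"
        )
    brass_rem = (wheel.brass_end - z) % 360.0
    spans = np.array([s.angular_span for s in wheel.steps])

    def rotation(t: float) -> float:
        """Rotation sweeping all steps with pull-back below ``t`` plus the
        matching fraction of the next step."""
        j = int(np.searchsorted(p, t))
        if j >= len(p):
            return brass_rem + spans.sum()
        f = (t - p[j - 1]) / (p[j] - p[j - 1]) if j > 0 else 1.0
        return brass_rem + spans[:j].sum() + max(f, 0.02) * spans[j]

    def width_error(t: float) -> float:
        proto = replay_delivery(wheel, z, rotation(t), request)
        dose, _ = _synthesize_raw(wheel, proto, request)
        try:
            return measure_modwidth(normalize_sobp(dose, request)) - m
        except ValueError:
            return float("inf")

    # Refine the swept pull-back span so the delivered D90-to-D90 width
    # matches the request.  The delivered width grows monotonically with the
    # swept span, so bisection applies.  For wide modulations the metric
    # sweeps up the slow proximal build-up and no span reproduces the
    # request; the nominal (geometric) span is then used unchanged.
    t_lo, t_hi = max(2.0, m - 25.0), min(float(p[-1]), m + 6.0)
    g_lo, g_hi = width_error(t_lo), width_error(t_hi)
    if not np.isfinite(g_lo) or g_lo > 0:
        t_star = min(m, float(p[-1]))
    elif g_hi <= 0 or not np.isfinite(g_hi):
        t_star = t_hi
    else:
        for _ in range(12):
            t_mid = 0.5 * (t_lo + t_hi)
            g_mid = width_error(t_mid)
            if not np.isfinite(g_mid) or g_mid > 0:
                t_hi = t_mid
            else:
                t_lo = t_mid
            if t_hi - t_lo < 0.3:
                break
        t_star = 0.5 * (t_lo + t_hi)
    return replay_delivery(wheel, z, rotation(t_star), request)


def _synthesize_raw(wheel: WheelSpec, protocol: DeliveryProtocol,
                    request: SobpRequest, grid: np.ndarray | None = None,
                    r80_mm: float | None = None):
    """Weighted superposition of pulled-back pristine curves (unnormalized)."""
    w = protocol.step_weights
    active = np.flatnonzero(w > 1e-12)
    if active.size == 0:
        raise ValueError("all-blocked sweep: no step receives beam")
    r80 = request.range_mm if r80_mm is None else r80_mm
    if grid is None:
        grid = np.arange(0.0, request.range_mm + 35.0 + 1e-9, 0.5)
    grid = np.asarray(grid, dtype=float)
    peak = pristine_for_request(request, r80)
    zf, df = _pristine_tables(peak, float(grid[-1]))
    letc = pristine_let(peak, grid)
    dose = np.zeros(grid.size)
    num = np.zeros(grid.size)
    pulls = wheel.pullbacks
    for i in active:
        d_i = np.interp(grid + pulls[i], zf, df, left=df[0], right=0.0)
        l_i = np.interp(grid + pulls[i], grid, letc.let, left=letc.let[0],
                        right=letc.let[-1])
        dose += w[i] * d_i
        num += w[i] * d_i * l_i
    let_d = np.where(dose > 1e-9 * dose.max(), num / np.maximum(dose, 1e-300), 0.0)
    return DepthDoseCurve(grid, dose), LetDepthCurve(grid, let_d)


def synthesize_sobp(wheel: WheelSpec, protocol: DeliveryProtocol,
                    request: SobpRequest, grid: np.ndarray | None = None):
    """Synthesize the delivered SOBP and its dose-averaged LET curve.

    Dose is the dwell-weighted sum of pulled-back pristine curves,
    normalized to mean 100 over the central half of the requested modulation
    width; LET_D(z) is the dose-weighted mean of the component LET curves.
    The beam energy (pristine range) is trimmed so the delivered distal D80
    matches the requested range.
    """
    dose, let = _synthesize_raw(wheel, protocol, request, grid)
    # vendor energy trim: pin delivered distal D80 to the requested range
    r80 = request.range_mm
    for _ in range(2):
        delivered = measure_range(normalize_sobp(dose, request))
        err = request.range_mm - delivered
        if abs(err) < 0.02:
            break
        r80 += err
        dose, let = _synthesize_raw(wheel, protocol, request, grid, r80_mm=r80)
    return normalize_sobp(dose, request), let


# ---------------------------------------------------------------------------
# YAML interchange

def wheel_to_yaml(wheel: WheelSpec, path) -> None:
    doc = {
        "center_plate_mm": float(wheel.center_plate_mm),
        "brass": {"start_deg": float(wheel.brass_start),
                  "span_deg": float(wheel.brass_span)},
        "rsp": {k: float(v) for k, v in wheel.material_rsp.items()},
        "steps": [
            {"angular_start": float(s.angular_start),
             "span": float(s.angular_span),
             "upstream_mm": float(s.upstream_mm),
             "downstream_mm": float(s.downstream_mm)}
            for s in wheel.steps
        ],
    }
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    tmp.replace(path)


def wheel_from_yaml(path) -> WheelSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        steps = tuple(
            WheelStep(float(s["angular_start"]), float(s["span"]),
                      float(s["upstream_mm"]), float(s["downstream_mm"]))
            for s in doc["steps"]
        )
        return WheelSpec(
            steps=steps,
            brass_start=float(doc["brass"]["start_deg"]),
            brass_span=float(doc["brass"]["span_deg"]),
            center_plate_mm=float(doc.get("center_plate_mm", 1.0)),
            material_rsp={k: float(v) for k, v in doc["rsp"].items()},
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"invalid wheel spec file {path}: {exc}") from exc
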