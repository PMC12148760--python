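"""Synthetic study inputs: wheels, measured SOBPs, pelvic phantoms, cohorts.

Everything the pipeline consumes is generated here, deterministically from
integer seeds: blueprint-like modulation wheels (the real blueprints are
proprietary), noisy "measured" SOBP curves delivered at a hidden zero-angle,
voxelized pelvic phantoms with body/CTV/PTV/bladder/rectum masks, and
patient cohorts grouped by two-field configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .curves import DepthDoseCurve, SobpRequest
from .dose3d import Field, StructureSet, VoxelPhantom
from .wheel import WheelSpec, WheelStep, rotation_for_modwidth, synthesize_sobp
from .calibration import Measurement, MeasurementSet

__all__ = [
    "TABLE1_REQUESTS",
    "FIELD_GROUPS",
    "SyntheticStudyConfig",
    "PatientSpec",
    "make_wheel",
    "draw_zero_angle",
    "make_measurements",
    "make_phantom",
    "make_cohort",
]

# The 11 delivery-QA configurations: (wheel number, requested range cm,
# requested modulation width cm). Six for wheel 1, five for wheel 2.
TABLE1_REQUESTS = {
    1: [
        SobpRequest(19.84, 3.00),
        SobpRequest(20.74, 11.50),
        SobpRequest(21.87, 15.90),
        SobpRequest(22.10, 6.00),
        SobpRequest(23.46, 11.00),
        SobpRequest(23.91, 16.00),
    ],
    2: [
        SobpRequest(22.90, 5.00),
        SobpRequest(25.61, 3.00),
        SobpRequest(26.29, 8.46),
        SobpRequest(28.32, 2.50),
        SobpRequest(28.40, 15.90),
    ],
}

# Symmetric two-field configurations (gantry angle pairs, deg); all within
# 10 degrees of lateral opposing.
FIELD_GROUPS = {
    "anterior_oblique": (82.0, 278.0),
    "lateral_opposing": (90.0, 270.0),
    "posterior_oblique": (98.0, 262.0),
}


@dataclass(frozen=True)
class SyntheticStudyConfig:
    seed: int = 0
    n_per_group: int = 5
    noise_sigma: float = 0.005
    anatomy_variability: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0.0 <= self.anatomy_variability <= 0.3):
            raise ValueError("anatomy_variability must lie in [0, 0.3]")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")


@dataclass(frozen=True)
class PatientSpec:
    patient_id: str
    group: str
    phantom_seed: int
    gantry_angles: tuple


def make_wheel(seed: int, n_steps: int = 80, max_pullback_mm: float = 165.0) -> WheelSpec:
    """Blueprint-like wheel with jittered angular spans and pull-back steps.

    The pull-back schedule rises from 0 to ``max_pullback_mm`` with
    irregular increments (real wheels are irregular by design; the
    irregularity is also what makes the zero-angle identifiable), the lead
    plate thins linearly while the low-Z plate thickens, and a brass block
    of 35-50 degrees separates the thickest from the thinnest step.  The
    default step count keeps pull-back increments comparable to the
    pristine-peak width so superpositions form a flat plateau.
    """
    if n_steps < 4:
        raise ValueError("need at least 4 steps")
    if max_pullback_mm < 160.0:
        raise ValueError("max pull-back must cover the largest requested "
                         "modulation width (160 mm)")
    rng = np.random.default_rng(seed)
    brass_span = float(rng.uniform(35.0, 50.0))
    spans = rng.uniform(0.7, 1.3, n_steps)
    spans *= (360.0 - brass_span) / spans.sum()
    incs = rng.uniform(0.7, 1.3, n_steps - 1)
    incs *= max_pullback_mm / incs.sum()
    pullbacks = np.concatenate([[0.0], np.cumsum(incs)])

    rsp = dict(WheelSpec.__dataclass_fields__["material_rsp"].default_factory())
    pb_max_mm = 2.0
    pb = np.linspace(pb_max_mm, 0.2, n_steps)  # lead thins with step index
    base_wet = rsp["aluminium"] * 1.0 + rsp["lead"] * pb_max_mm + 1.0
    wets = base_wet + pullbacks
    up = (wets - rsp["aluminium"] * 1.0 - rsp["lead"] * pb) / rsp["lowz"]

    brass_start = float(rng.uniform(0.0, 360.0))
    steps = []
    a = brass_start + brass_span
    for i in range(n_steps):
        steps.append(WheelStep(a % 360.0, float(spans[i]), float(up[i]), float(pb[i])))
        a += spans[i]
    return WheelSpec(steps=tuple(steps), brass_start=brass_start % 360.0,
                     brass_span=brass_span, material_rsp=rsp)


def draw_zero_angle(wheel: WheelSpec, seed: int) -> float:
    """Hidden hardware zero-angle: inside the central 60% of the brass block."""
    rng = np.random.default_rng(seed)
    return float((wheel.brass_start
                  + wheel.brass_span * rng.uniform(0.2, 0.8)) % 360.0)


def make_measurements(wheel: WheelSpec, hidden_zero_angle: float, requests,
                      noise_sigma: float, seed: int) -> MeasurementSet:
    """Synthetic water-phantom SOBP measurements delivered at a hidden
    zero-angle, sampled every 0.5 mm with multiplicative Gaussian noise.

    Each entry records the machine rotation angle of its delivery -- known
    metadata that calibration replays at candidate zero-angles.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for req in requests:
        proto = rotation_for_modwidth(wheel, hidden_zero_angle, req)
        dose, _ = synthesize_sobp(wheel, proto, req)
        scale = rng.uniform(0.8, 1.2)  # chamber readings in arbitrary units
        noisy = dose.dose * scale * (1.0 + noise_sigma * rng.standard_normal(dose.dose.size))
        noisy = np.maximum(noisy, 0.0)
        entries.append(Measurement(req, proto.rotation_angle,
                                   DepthDoseCurve(dose.depths, noisy)))
    return MeasurementSet(tuple(entries))


def _ellipsoid(centers, center, semi):
    X, Y, Z = centers
    return (((X[:, None, None] - center[0]) / semi[0]) ** 2
            + ((Y[None, :, None] - center[1]) / semi[1]) ** 2
            + ((Z[None, None, :] - center[2]) / semi[2]) ** 2) <= 1.0


def make_phantom(seed: int, variability: float = 0.05, spacing_mm: float = 3.0,
                 bone_inserts: bool = False, retries: int = 5):
    """Voxelized pelvic phantom with organ masks.

    Elliptical soft-tissue body (~360 x 240 mm axial), near-spherical CTV at
    mid-pelvis, bladder abutting anterior-superior, rectal tube posterior;
    the PTV is the CTV expanded 6 mm axially and 8 mm superior-inferior.
    Sizes and positions are jittered by ``variability``.
    """
    if not (0.0 <= variability <= 0.3):
        raise ValueError("variability must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    last_err = None
    for _ in range(retries):
        try:
            return _build_phantom(rng, variability, spacing_mm, bone_inserts)
        except ValueError as exc:  # geometry violated an invariant; redraw
            last_err = exc
    raise ValueError(f"could not generate a valid phantom: {last_err}")


def _build_phantom(rng, variability, h, bone_inserts):
    def jit(scale=1.0):
        return 1.0 + variability * scale * rng.uniform(-1.0, 1.0)

    body_a = 180.0 * jit()   # patient-left/right semi-axis, mm
    body_b = 120.0 * jit()   # anterior-posterior semi-axis, mm
    nx = int(np.ceil(2 * (body_a + 6.0) / h))
    ny = int(np.ceil(2 * (body_b + 6.0) / h))
    nz = int(np.ceil(96.0 / h))
    shape = (nx, ny, nz)
    origin = (-(nx - 1) / 2 * h, -(ny - 1) / 2 * h, -(nz - 1) / 2 * h)
    xs = origin[0] + h * np.arange(nx)
    ys = origin[1] + h * np.arange(ny)
    zs = origin[2] + h * np.arange(nz)
    centers = (xs, ys, zs)

    body = ((xs[:, None, None] / body_a) ** 2
            + (ys[None, :, None] / body_b) ** 2) <= 1.0
    body = np.broadcast_to(body, shape).copy()

    ctv_r = 22.5 * jit()
    ctv_c = (0.0 + 20.0 * variability * rng.uniform(-1, 1),
             15.0 + 20.0 * variability * rng.uniform(-1, 1),
             0.0)
    ctv = _ellipsoid(centers, ctv_c, (ctv_r, ctv_r, ctv_r))

    # PTV: anisotropic expansion, 6 mm axial and 8 mm superior-inferior
    edt = distance_transform_edt(~ctv, sampling=(h / 6.0, h / 6.0, h / 8.0))
    ptv = edt <= 1.0

    bladder_semi = (34.0 * jit(), 25.0 * jit(), 26.0 * jit())
    bladder_c = (ctv_c[0], ctv_c[1] - ctv_r - bladder_semi[1] + 3.0, 14.0)
    bladder = _ellipsoid(centers, bladder_c, bladder_semi) & ~ptv

    rect_r = 14.0 * jit()
    rect_c = (ctv_c[0], ctv_c[1] + ctv_r + rect_r - 3.0, 0.0)
    rectum = _ellipsoid(centers, rect_c, (rect_r, rect_r, 1e9)) & ~ptv

    rsp = np.full(shape, 0.001)
    rsp[body] = 1.0
    if bone_inserts:
        for sgn in (-1.0, 1.0):
            head = _ellipsoid(centers, (sgn * 120.0, 10.0, 0.0), (22.0, 22.0, 22.0))
            rsp[head & body] = 1.5

    structures = StructureSet({
        "body": body, "ctv": ctv, "ptv": ptv & body,
        "bladder": bladder & body, "rectum": rectum & body,
    })
    phantom = VoxelPhantom(origin, (h, h, h), rsp)
    if not structures["bladder"].any() or not structures["rectum"].any():
        raise ValueError("organ mask empty")
    return phantom, structures


def make_cohort(config: SyntheticStudyConfig):
    """Patient specs: one phantom seed and one symmetric field pair each.

    Groups partition the cohort with ``n_per_group`` patients per field
    configuration; angle pairs are the three reference configurations
    (82/278 anterior oblique, 90/270 lateral, 98/262 posterior oblique).
    """
    specs = []
    for gi, (group, angles) in enumerate(sorted(FIELD_GROUPS.items())):
        for k in range(config.n_per_group):
            specs.append(PatientSpec(
                patient_id=f"{group[:3]}{k:03d}",
                group=group,
                phantom_seed=int(config.seed * 10007 + k) % (2**31),
                gantry_angles=angles,
            ))
    return specs


def cohort_fields(spec: PatientSpec):
    """The two broad-beam fields of a patient's plan."""
    return [Field(gantry_angle=a) for a in spec.gantry_angles]
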