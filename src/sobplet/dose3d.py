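"""Broad-beam two-field dose and dose-averaged LET on a voxel phantom.

Each treatment field is an idealized broad beam: the delivered SOBP (from
the wheel model) is looked up at every voxel's radiological depth, and an
aperture shaped to the PTV's beam's-eye-view projection plus a margin
applies an error-function lateral rolloff with a parametric penumbra sigma.
Lateral scatter microstructure, range compensators and absolute dosimetry
are out of scope; per-plan dose is normalized to the median CTV dose.

Axes: index order (x, y, z) with +x patient-left, +y posterior, +z
superior.  Gantry angles are IEC-like in the axial plane: 0 = anterior,
90 = beam entering from patient-left; a symmetric pair (g, 360-g) mirrors
through the sagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates
from scipy.special import erfc

from .curves import SobpRequest
from .wheel import WheelSpec, rotation_for_modwidth, synthesize_sobp

__all__ = [
    "VoxelPhantom",
    "StructureSet",
    "Field",
    "DoseLetGrids",
    "beam_direction",
    "radiological_depth",
    "field_dose_let",
    "plan_dose_let",
]

REQUIRED_MASKS = ("body", "ctv", "ptv", "bladder", "rectum")


@dataclass(frozen=True)
class VoxelPhantom:
    """Relative-stopping-power grid (water = 1) with mm origin and spacing."""

    origin: tuple
    spacing: tuple
    rsp: np.ndarray

    def __post_init__(self) -> None:
        origin = tuple(float(v) for v in self.origin)
        spacing = tuple(float(v) for v in self.spacing)
        rsp = np.asarray(self.rsp, dtype=float)
        if rsp.ndim != 3:
            raise ValueError("rsp grid must be 3-D")
        if len(origin) != 3 or len(spacing) != 3:
            raise ValueError("origin and spacing must be length-3")
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(rsp)) or np.any(rsp < 0):
            raise ValueError("rsp must be finite and non-negative")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "rsp", rsp)

    @property
    def shape(self):
        return self.rsp.shape

    def voxel_centers(self):
        """Coordinate arrays (1-D per axis) of voxel centres in mm."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


@dataclass(frozen=True)
class StructureSet:
    """Named binary masks congruent with the phantom grid."""

    masks: dict

    def __post_init__(self) -> None:
        masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        for key in REQUIRED_MASKS:
            if key not in masks:
                raise ValueError(f"missing structure mask {key!r}")
        shapes = {m.shape for m in masks.values()}
        if len(shapes) != 1:
            raise ValueError("all masks must share one grid shape")
        if np.any(masks["ctv"] & ~masks["ptv"]):
            raise ValueError("CTV must be contained in PTV")
        if np.any(masks["ptv"] & ~masks["body"]):
            raise ValueError("PTV must be contained in the body")
        if np.any(masks["bladder"] & masks["rectum"]):
            raise ValueError("bladder and rectum must not overlap")
        object.__setattr__(self, "masks", masks)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.masks[key]


@dataclass(frozen=True)
class Field:
    """One broad-beam field of a two-field plan.

    ``sobp=None`` lets the planner choose range and modulation from the
    PTV's radiological depth extent (range margin 5 mm distal, modulation
    covering the PTV extent plus 5 mm on each side).
    """

    gantry_angle: float
    sobp: SobpRequest | None = None
    aperture_margin: float = 7.0
    penumbra_sigma: float = 5.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("field weight must be positive")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be positive")


@dataclass(frozen=True)
class DoseLetGrids:
    dose: np.ndarray
    let_d: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        let_d = np.asarray(self.let_d, dtype=float)
        if dose.shape != let_d.shape:
            raise ValueError("dose and let_d grids must be congruent")
        if np.any(dose < 0) or np.any(let_d < 0):
            raise ValueError("dose and let_d must be non-negative")
        if np.any((dose == 0) & (let_d != 0)):
            raise ValueError("let_d must vanish wherever dose vanishes")
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "let_d", let_d)


def beam_direction(gantry_angle: float) -> np.ndarray:
    """Unit propagation vector in the axial plane for an IEC-like angle."""
    g = np.deg2rad(gantry_angle)
    return np.array([-np.sin(g), np.cos(g), 0.0])


def radiological_depth(phantom: VoxelPhantom, direction) -> np.ndarray:
    """Water-equivalent depth of every voxel centre along ``-direction``.

    Uniform ray stepping (midpoint rule, step = half the smallest axial
    spacing) of the RSP grid from the grid boundary to each voxel centre;
    air outside the grid contributes nothing.
    """
    u = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("beam direction must be non-zero")
    if abs(u[2]) > 1e-9 * norm:
        raise ValueError("beam direction must lie in the axial plane")
    u = u / norm
    sx, sy, sz = phantom.spacing
    step = 0.5 * min(sx, sy)
    nx, ny, nz = phantom.shape
    # extent of the grid along the beam axis bounds the marching length
    extent = abs(u[0]) * nx * sx + abs(u[1]) * ny * sy
    n_steps = int(np.ceil(extent / step)) + 1

    ix, iy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                         indexing="ij")
    # per-axis index displacement of one upstream step
    du = -u * step
    dix, diy = du[0] / sx, du[1] / sy
    depth = np.zeros((nx, ny, nz))
    coords_z = np.arange(nz, dtype=float)
    for k in range(n_steps):
        off_x = ix + dix * (k + 0.5)
        off_y = iy + diy * (k + 0.5)
        cx = np.broadcast_to(off_x[..., None], (nx, ny, nz)).ravel()
        cy = np.broadcast_to(off_y[..., None], (nx, ny, nz)).ravel()
        cz = np.broadcast_to(coords_z[None, None, :], (nx, ny, nz)).ravel()
        vals = map_coordinates(phantom.rsp, [cx, cy, cz], order=1, mode="constant",
                               cval=0.0, prefilter=False)
        depth += vals.reshape(nx, ny, nz) * step
    return depth


def _lateral_transmission(phantom: VoxelPhantom, ptv: np.ndarray, u: np.ndarray,
                          margin: float, sigma: float) -> np.ndarray:
    """Aperture transmission per voxel: erf rolloff around the PTV
    beam's-eye-view projection expanded by ``margin``."""
    xs, ys, zs = phantom.voxel_centers()
    v_axis = np.array([u[1], -u[0]])  # unit vector perpendicular to u, axial
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    V2d = v_axis[0] * X + v_axis[1] * Y  # lateral coordinate, same for all z
    h = min(phantom.spacing[0], phantom.spacing[1])
    # bin grid centred on v = 0 so mirrored fields share the same lattice
    half = int(np.ceil((np.abs(V2d).max() + 2 * h) / h))
    v_min = -half * h
    nv = 2 * half + 1
    # occupancy of the PTV projection in (v, z) bins
    occ = np.zeros((nv, phantom.shape[2]), dtype=bool)
    pidx = np.nonzero(ptv)
    if pidx[0].size == 0:
        raise ValueError("PTV mask is empty")
    v_vox = V2d[pidx[0], pidx[1]]
    vbin = np.clip(np.round((v_vox - v_min) / h).astype(int), 0, nv - 1)
    occ[vbin, pidx[2]] = True
    # signed distance to the projection boundary (positive outside), mm
    sampling = (h, phantom.spacing[2])
    d_out = distance_transform_edt(~occ, sampling=sampling)
    d_in = distance_transform_edt(occ, sampling=sampling)
    signed = np.where(occ, -d_in, d_out)
    trans2d = 0.5 * erfc((signed - margin) / (np.sqrt(2.0) * sigma))
    # sample per voxel (bilinear in the (v, z) map)
    vi = (V2d[..., None] - v_min) / h
    vi = np.broadcast_to(vi, phantom.shape)
    zi = np.broadcast_to(np.arange(phantom.shape[2], dtype=float)[None, None, :],
                         phantom.shape)
    return map_coordinates(trans2d, [vi.ravel(), zi.ravel()], order=1,
                           mode="nearest").reshape(phantom.shape)


def _auto_request(depths_ptv: np.ndarray, wheel: WheelSpec) -> SobpRequest:
    d_max = float(depths_ptv.max())
    d_min = float(depths_ptv.min())
    range_mm = d_max + 5.0
    mod_mm = min(d_max - d_min + 10.0, wheel.max_pullback, range_mm)
    mod_mm = max(mod_mm, 25.0)
    return SobpRequest(range_cm=range_mm / 10.0, modwidth_cm=mod_mm / 10.0)


def field_dose_let(phantom: VoxelPhantom, structures: StructureSet, field: Field,
                   wheel: WheelSpec, zero_angle: float) -> DoseLetGrids:
    """Dose and LET_D grids for a single broad-beam field."""
    u = beam_direction(field.gantry_angle)
    rd = radiological_depth(phantom, u)
    ptv = structures["ptv"]
    depths_ptv = rd[ptv]
    if field.sobp is None:
        request = _auto_request(depths_ptv, wheel)
    else:
        request = field.sobp
        uncovered = float(np.mean(depths_ptv > request.range_mm))
        if uncovered > 0:
            raise ValueError(
                f"SOBP range {request.range_mm:.1f} mm leaves {100 * uncovered:.1f}% "
                "of PTV voxels beyond the distal edge"
            )
    proto = rotation_for_modwidth(wheel, zero_angle, request)
    grid = np.arange(0.0, max(request.range_mm + 35.0, rd.max() + 1.0), 0.5)
    sobp, letc = synthesize_sobp(wheel, proto, request, grid)
    dose_z = np.interp(rd, sobp.depths, sobp.dose, left=sobp.dose[0], right=0.0)
    let_z = np.interp(rd, letc.depths, letc.let, left=letc.let[0], right=0.0)
    trans = _lateral_transmission(phantom, ptv, u, field.aperture_margin,
                                  field.penumbra_sigma)
    dose = field.weight * dose_z * trans
    dose[dose < 1e-9] = 0.0
    let = np.where(dose > 0, let_z, 0.0)
    return DoseLetGrids(dose, let)


def plan_dose_let(field_grids, prescription: float, ctv_mask: np.ndarray) -> DoseLetGrids:
    """Combine fields: total dose rescaled so the median CTV dose equals the
    prescription; LET_D is the dose-weighted mean of the field LET grids."""
    grids = list(field_grids)
    if not grids:
        raise ValueError("need at least one field")
    shapes = {g.dose.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError("field grids must be congruent")
    ctv = np.asarray(ctv_mask, dtype=bool)
    if not ctv.any():
        raise ValueError("CTV mask is empty")
    total = np.zeros_like(grids[0].dose)
    num = np.zeros_like(grids[0].dose)
    for g in grids:
        total += g.dose
        num += g.dose * g.let_d
    med = float(np.median(total[ctv]))
    if med <= 0:
        raise ValueError("median CTV dose is zero; cannot normalize")
    let = np.where(total > 0, num / np.maximum(total, 1e-300), 0.0)
    return DoseLetGrids(total * (prescription / med), let)
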