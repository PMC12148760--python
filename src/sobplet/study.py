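"""End-to-end study orchestration: calibration, cohort, LET analysis.

``run_study`` chains the full desk-scale analysis from one YAML config:
build two synthetic wheels, calibrate their zero-angles against noisy
synthetic measurements and emit the validation table; generate a pelvic
phantom cohort grouped by field configuration; compute per-patient two-field
dose and LET_D grids with a gamma self-check (recalculated dose at the
calibrated zero-angle versus the delivered dose at the hidden zero-angle);
and summarize the bladder-to-rectum LET_D(D_T) ratio curves per group.

All outputs are plain text (CSV tables, ASCII NRRD grids, YAML specs, JSON
manifest); file writes are atomic and every run writes a manifest recording
version, config hash, seed and per-stage timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate, validate, validation_frame
from .dose3d import field_dose_let, plan_dose_let
from .gamma import GammaCriteria, gamma_pass_rate
from .let_metrics import (
    bladder_rectum_ratio,
    group_summary,
    let_dt_curve,
    mean_let_above,
)
from .nrrd_io import write_nrrd
from .synthetic import (
    FIELD_GROUPS,
    TABLE1_REQUESTS,
    SyntheticStudyConfig,
    cohort_fields,
    draw_zero_angle,
    make_cohort,
    make_measurements,
    make_phantom,
    make_wheel,
)
from .wheel import wheel_to_yaml

logger = logging.getLogger("sobplet")

__all__ = [
    "DEFAULT_CONFIG",
    "calibrate_wheels",
    "patient_dose_let",
    "cohort_analysis",
    "run_study",
]

DEFAULT_CONFIG = {
    "seed": 1,
    "n_per_group": 2,
    "noise_sigma": 0.005,
    "anatomy_variability": 0.05,
    "voxel_mm": 3.0,
    "prescription_gy": 78.0,
}


def calibrate_wheels(seed: int, noise_sigma: float = 0.005):
    """Build both wheels, synthesize their delivery-QA measurements at hidden
    zero-angles, run the two-stage search, and validate.

    Returns a dict per wheel number with the wheel, hidden and recovered
    zero-angles, the measurement set, and the validation rows.
    """
    out = {}
    for wheel_no, requests in TABLE1_REQUESTS.items():
        wheel = make_wheel(seed=(seed * 101 + wheel_no) % (2**31))
        hidden = draw_zero_angle(wheel, seed=(seed * 211 + wheel_no) % (2**31))
        meas = make_measurements(wheel, hidden, requests, noise_sigma,
                                 seed=(seed * 307 + wheel_no) % (2**31))
        recovered = calibrate(meas, wheel)
        rows = validate(meas, wheel, recovered)
        out[wheel_no] = {
            "wheel": wheel, "hidden_zero_angle": hidden,
            "recovered_zero_angle": recovered, "measurements": meas,
            "rows": rows,
        }
    return out


def patient_dose_let(phantom, structures, angles, wheel, zero_angle,
                     prescription_gy: float = 78.0):
    """Two-field plan dose/LET_D grids for one patient."""
    from .dose3d import Field

    grids = [
        field_dose_let(phantom, structures, Field(gantry_angle=a), wheel, zero_angle)
        for a in angles
    ]
    return plan_dose_let(grids, prescription_gy, structures["ctv"])


def cohort_analysis(seed: int, n_per_group: int, wheel, zero_angle,
                    anatomy_variability: float = 0.05, voxel_mm: float = 3.0,
                    prescription_gy: float = 78.0):
    """Dose/LET_D for a matched cohort (same phantoms, three field groups).

    Returns per-patient organ LET_D(D_T) ratio curves grouped by field
    configuration, group summaries, and per-patient organ means at the 10
    and 70 Gy iso-dose levels.
    """
    cfg = SyntheticStudyConfig(seed=seed, n_per_group=n_per_group,
                               anatomy_variability=anatomy_variability)
    specs = make_cohort(cfg)
    phantoms = {}
    ratio_curves = {g: [] for g in FIELD_GROUPS}
    records = []
    for spec in specs:
        if spec.phantom_seed not in phantoms:
            phantoms[spec.phantom_seed] = make_phantom(
                spec.phantom_seed, cfg.anatomy_variability, voxel_mm)
        phantom, structures = phantoms[spec.phantom_seed]
        plan = patient_dose_let(phantom, structures, spec.gantry_angles, wheel,
                                zero_angle, prescription_gy)
        bl = let_dt_curve(plan.dose, plan.let_d, structures["bladder"])
        re_ = let_dt_curve(plan.dose, plan.let_d, structures["rectum"])
        ratio_curves[spec.group].append(bladder_rectum_ratio(bl, re_))
        for iso in (10.0, 70.0):
            records.append({
                "patient_id": spec.patient_id, "group": spec.group,
                "d_t_gy": iso,
                "bladder_mean_let_kev_um":
                    mean_let_above(plan.dose, plan.let_d, structures["bladder"], iso),
                "rectum_mean_let_kev_um":
                    mean_let_above(plan.dose, plan.let_d, structures["rectum"], iso),
            })
    summaries = {}
    if n_per_group >= 2:
        summaries = {g: group_summary(cs, g) for g, cs in ratio_curves.items()}
    return {
        "ratio_curves": ratio_curves,
        "summaries": summaries,
        "organ_means": pd.DataFrame.from_records(records),
    }


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    _atomic_write_text(path, frame.to_csv(index=False))


def load_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(doc) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(doc)
    return cfg


def run_study(config, out_dir, resume: bool = False) -> Path:
    """Run the whole desk-scale study; returns the result directory.

    ``config`` is a YAML path or a dict with keys of ``DEFAULT_CONFIG``.
    With ``resume=True``, stages whose outputs already exist are skipped;
    outputs are deterministic for a fixed config.
    """
    cfg = load_config(config) if not isinstance(config, dict) else {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    timings = {}
    manifest_outputs = []

    def stage(name):
        logger.info("stage %s (seed=%d)", name, seed)
        timings[name] = -time.perf_counter()

    def done(name):
        timings[name] += time.perf_counter()

    # --- calibration -------------------------------------------------------
    calib_csv = out / "calibration_report.csv"
    stage("calibrate")
    calib = calibrate_wheels(seed, cfg["noise_sigma"])
    frames = []
    for wheel_no, res in calib.items():
        wheel_yaml = out / f"wheel{wheel_no}.yaml"
        if not (resume and wheel_yaml.exists()):
            wheel_to_yaml(res["wheel"], wheel_yaml)
        manifest_outputs.append(wheel_yaml.name)
        f = validation_frame(res["rows"])
        f.insert(0, "wheel", wheel_no)
        f["recovered_zero_angle_deg"] = res["recovered_zero_angle"]
        frames.append(f)
    if not (resume and calib_csv.exists()):
        _write_csv(pd.concat(frames, ignore_index=True), calib_csv)
    manifest_outputs.append(calib_csv.name)
    done("calibrate")

    wheel1 = calib[1]["wheel"]
    z_true = calib[1]["hidden_zero_angle"]
    z_cal = calib[1]["recovered_zero_angle"]

    # --- cohort dose/LET and gamma self-check ------------------------------
    stage("cohort")
    scfg = SyntheticStudyConfig(seed=seed, n_per_group=int(cfg["n_per_group"]),
                                noise_sigma=cfg["noise_sigma"],
                                anatomy_variability=cfg["anatomy_variability"])
    specs = make_cohort(scfg)
    phantoms = {}
    gamma_rows = []
    manifest_rows = []
    ratio_curves = {g: [] for g in FIELD_GROUPS}
    organ_records = []
    for spec in specs:
        if spec.phantom_seed not in phantoms:
            phantoms[spec.phantom_seed] = make_phantom(
                spec.phantom_seed, scfg.anatomy_variability, cfg["voxel_mm"])
        phantom, structures = phantoms[spec.phantom_seed]
        pdir = out / "patients" / spec.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        plan_path = pdir / "plan.yaml"
        if not (resume and plan_path.exists()):
            _atomic_write_text(plan_path, yaml.safe_dump({
                "patient_id": spec.patient_id, "group": spec.group,
                "prescription_gy": cfg["prescription_gy"],
                "fields": [{"gantry_angle": float(a), "weight": 1.0}
                           for a in spec.gantry_angles],
            }, sort_keys=False))
        # "planning" dose: delivered at the true (hidden) zero-angle
        planning = patient_dose_let(phantom, structures, spec.gantry_angles,
                                    wheel1, z_true, cfg["prescription_gy"])
        # recalculation at the calibrated zero-angle
        recalc = patient_dose_let(phantom, structures, spec.gantry_angles,
                                  wheel1, z_cal, cfg["prescription_gy"])
        for name, arr in (("dose_gy", recalc.dose), ("let_d_kev_um", recalc.let_d),
                          ("rsp", phantom.rsp)):
            p = pdir / f"{name}.nrrd"
            if not (resume and p.exists()):
                write_nrrd(p, arr, phantom.origin, phantom.spacing)
        for mname, m in structures.masks.items():
            p = pdir / f"mask_{mname}.nrrd"
            if not (resume and p.exists()):
                write_nrrd(p, m.astype(np.int8), phantom.origin, phantom.spacing)
        for dd, dta in ((3.0, 3.0), (2.0, 2.0)):
            res = gamma_pass_rate(planning.dose, recalc.dose, phantom.spacing,
                                  GammaCriteria(dd_percent=dd, dta_mm=dta))
            gamma_rows.append({
                "patient_id": spec.patient_id, "group": spec.group,
                "dd_percent": dd, "dta_mm": dta,
                "pass_rate_percent": res.pass_rate,
                "evaluated_voxels": res.evaluated_count,
            })
        bl = let_dt_curve(recalc.dose, recalc.let_d, structures["bladder"])
        re_ = let_dt_curve(recalc.dose, recalc.let_d, structures["rectum"])
        ratio_curves[spec.group].append(bladder_rectum_ratio(bl, re_))
        for iso in (10.0, 70.0):
            organ_records.append({
                "patient_id": spec.patient_id, "group": spec.group, "d_t_gy": iso,
                "bladder_mean_let_kev_um": mean_let_above(
                    recalc.dose, recalc.let_d, structures["bladder"], iso),
                "rectum_mean_let_kev_um": mean_let_above(
                    recalc.dose, recalc.let_d, structures["rectum"], iso),
            })
        manifest_rows.append({"patient_id": spec.patient_id, "group": spec.group,
                              "phantom_seed": spec.phantom_seed,
                              "gantry_angles": "/".join(str(a) for a in
                                                        spec.gantry_angles)})
    _write_csv(pd.DataFrame(gamma_rows), out / "gamma_self_check.csv")
    _write_csv(pd.DataFrame(manifest_rows), out / "cohort_manifest.csv")
    _write_csv(pd.DataFrame.from_records(organ_records), out / "organ_mean_let.csv")
    manifest_outputs += ["gamma_self_check.csv", "cohort_manifest.csv",
                         "organ_mean_let.csv"]
    done("cohort")

    # --- group LET summaries ------------------------------------------------
    stage("letstats")
    if scfg.n_per_group >= 2:
        frames = [group_summary(cs, g).frame() for g, cs in ratio_curves.items()]
        _write_csv(pd.concat(frames, ignore_index=True),
                   out / "group_ratio_summary.csv")
        manifest_outputs.append("group_ratio_summary.csv")
    done("letstats")

    cfg_text = json.dumps(cfg, sort_keys=True)
    manifest = {
        "tool": "sobplet", "version": __version__,
        "config": cfg, "seed": seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "outputs": manifest_outputs,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    _atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2) + "\n")
    return out
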