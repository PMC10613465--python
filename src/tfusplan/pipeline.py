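"""End-to-end planning pipeline.

Stage order: anatomy (phantom or CT volume) -> skull mask -> acoustic
property maps -> target -> RP candidate matrix -> per-candidate pressure
simulation -> peak selection -> transcranial + free-water field at the
chosen pose -> focal metrics and deviation -> safety indices -> bioheat.
Every stage's artifacts are written under the configured output directory;
a run is fully reproducible from its config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PlanningConfig, config_hash, validate_config
from .metrics import beam_angles, deviation_vs_water, extract_fwhm, safety_indices
from .positioning import (
    TargetSpec,
    candidate_matrix,
    control_group_placement,
    evaluate_pose,
    position_transducer,
)
from .properties import MediumMaps, PropertyConstants, property_maps
from .pulse import derive_timing
from .thermal import ThermalProperties, heat_deposition, solve_pennes, thermal_safety_report
from .volumes import binarize_skull, generate_phantom, load_nifti, resample_isotropic, save_nifti

__all__ = ["PlanningReport", "run_pipeline"]

log = logging.getLogger("tfusplan")

REPORT_COLUMNS = [
    "frequency_hz", "chosen_x_mm", "chosen_y_mm", "chosen_z_mm",
    "angle_transverse_deg", "angle_sagittal_deg", "angle_coronal_deg",
    "stimulus_distance_mm", "n_candidates", "n_evaluated",
    "excl_inside_skull", "excl_below_average_radius", "excl_contact_clearance",
    "fwhm_length_water_mm", "fwhm_width_water_mm", "fwhm_offset_water_deg",
    "fwhm_length_skull_mm", "fwhm_width_skull_mm", "fwhm_offset_skull_deg",
    "deviation_length_mm", "deviation_length_pct", "deviation_width_mm",
    "deviation_width_pct", "deviation_offset_deg", "amplitude_drop_pct",
    "peak_amplitude_pa", "mi", "i_sppa_w_cm2", "i_spta_mw_cm2",
    "fda_mi_ok", "fda_isppa_ok", "peak_temperature_c",
    "exceeds_42", "exceeds_47", "exceeds_50",
]


@dataclass
class PlanningReport:
    """Per-frequency planning rows plus provenance."""

    rows: list
    config_hash: str
    seed: int
    runtime: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=REPORT_COLUMNS)

    def to_json(self, include_runtime: bool = True) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "rows": self.rows,
        }
        if include_runtime:
            payload["runtime"] = self.runtime
        return json.dumps(payload, indent=2, sort_keys=True, default=float)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "report.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())


def _build_anatomy(cfg: PlanningConfig):
    if cfg.phantom is not None:
        hu = generate_phantom(cfg.phantom)
    else:
        hu = load_nifti(cfg.input_nifti)
    if not np.allclose(hu.spacing, cfg.resample_spacing):
        hu = resample_isotropic(hu, cfg.resample_spacing)
    mask = binarize_skull(hu, cfg.hu_threshold)
    return hu, mask


def run_pipeline(config: PlanningConfig, write_artifacts: bool = True) -> PlanningReport:
    """Execute the full planning chain for every configured frequency."""
    t_start = time.perf_counter()
    cfg = validate_config(config)
    outdir = Path(cfg.output_dir)
    stage = "anatomy"
    timings: dict = {}
    try:
        hu, mask = _build_anatomy(cfg)
        log.info("anatomy: %s voxels, %d skull voxels", hu.shape, mask.data.sum())
        stage = "properties"
        const = PropertyConstants(power_law_exponent=cfg.solver.power_law_exponent)
        medium = property_maps(hu, mask, const)
        stage = "target"
        target_pt = cfg.target_point or (
            cfg.phantom.target_point if cfg.phantom else None
        )
        if target_pt is None:
            raise ValueError("no target point configured")
        target = TargetSpec(point=tuple(target_pt))
        stage = "candidate_matrix"
        cands = candidate_matrix(
            mask,
            target,
            roc=cfg.transducer.radius_of_curvature,
            clearance=cfg.rp.clearance,
            transducer=cfg.transducer,
            ball_radius_margin=cfg.rp.ball_radius_margin,
        )
        log.info(
            "candidate matrix: %d candidates (excluded %s)",
            cands.n_candidates, cands.excluded,
        )
        if write_artifacts:
            outdir.mkdir(parents=True, exist_ok=True)
            save_nifti(hu, outdir / "hu_volume.nii.gz")
            save_nifti(mask, outdir / "skull_mask.nii.gz")
        timings["setup_s"] = time.perf_counter() - t_start

        rows = []
        duty = derive_timing(cfg.pulse).duty_cycle
        for f in cfg.frequencies:
            t_f = time.perf_counter()
            stage = f"positioning@{f:.0f}Hz"
            drive = dataclasses.replace(cfg.pulse, fundamental_frequency=f)
            spec = dataclasses.replace(cfg.transducer, drive=drive)
            controls = control_group_placement(
                target,
                spec.radius_of_curvature,
                angles=cfg.control_angles,
                planes=cfg.control_planes,
            )
            pos = position_transducer(
                cands, target, spec, medium, drive,
                mode=cfg.solver.mode,
                subsample=cfg.rp.subsample,
                max_candidates=cfg.rp.max_candidates,
                seed=cfg.rp.seed,
                control_poses=controls,
                cfl=cfg.solver.cfl,
                pml_width=cfg.solver.pml_width,
                settle_periods=cfg.solver.settle_periods,
                measure_periods=cfg.solver.measure_periods,
                spacing=cfg.solver.spacing,
            )
            log.info(
                "%.0f kHz: chosen %s, %.0f Pa at target (%d candidates, %d failures)",
                f / 1e3, np.round(pos.chosen_center, 1), pos.chosen_amplitude,
                pos.candidate_amplitudes.size, pos.failures,
            )
            stage = f"fields@{f:.0f}Hz"
            # focal-geometry fields are time-gated to the direct arrival so
            # reverberation in the closed cavity does not widen the focus
            common = dict(
                mode=cfg.solver.mode, cfl=cfg.solver.cfl,
                pml_width=cfg.solver.pml_width,
                settle_periods=cfg.solver.settle_periods,
                measure_periods=cfg.solver.measure_periods,
                spacing=cfg.solver.spacing, return_field=True,
                first_arrival_gate=True,
            )
            _, field_s, grid_s, _, med_s = evaluate_pose(
                medium, pos.chosen_center, target.point, spec, drive, **common
            )
            water = MediumMaps.homogeneous_water(
                medium.shape, medium.spacing, medium.origin, const
            )
            _, field_w, _, _, _ = evaluate_pose(
                water, pos.chosen_center, target.point, spec, drive, **common
            )
            stage = f"metrics@{f:.0f}Hz"
            nd = field_s.amplitude.ndim
            axis = np.zeros(nd)
            axis[0] = 1.0  # beam axis is the first plane coordinate in 2D mode
            if cfg.solver.mode == "3d":
                axis = np.asarray(target.point) - pos.chosen_center
                axis = axis / np.linalg.norm(axis)
            # anchor the focal analysis near the target voxel so standing
            # waves between the bowl and the skull are not mistaken for it
            hint = field_s.probe_indices.get("target")
            fm_s = extract_fwhm(field_s.amplitude, axis, spacing=grid_s.spacing,
                                focus_hint=hint)
            fm_w = extract_fwhm(field_w.amplitude, axis, spacing=grid_s.spacing,
                                focus_hint=hint)
            dev = deviation_vs_water(fm_s, fm_w)
            geom = beam_angles(pos.chosen_center, target.point)
            p_neg = field_s.peak_negative_pressure.get(
                "target", fm_s.peak_amplitude
            )
            safety = safety_indices(p_neg, f, duty_cycle=duty)
            stage = f"thermal@{f:.0f}Hz"
            skull_vox = med_s.sound_speed > const.c_water + 1.0
            thermal_props = ThermalProperties.from_medium(med_s, skull_mask=skull_vox)
            sd = cfg.pulse.sonication_duration
            src_q = heat_deposition(
                field_s.amplitude, med_s, f, duty_cycle=duty, schedule=[(0.0, sd)]
            )
            th = solve_pennes(
                thermal_props, src_q,
                duration=cfg.thermal.duration,
                t0=cfg.thermal.baseline_temperature,
                dt=cfg.thermal.dt,
            )
            th_report = thermal_safety_report(th)
            rows.append({
                "frequency_hz": f,
                "chosen_x_mm": float(pos.chosen_center[0]),
                "chosen_y_mm": float(pos.chosen_center[1]),
                "chosen_z_mm": float(pos.chosen_center[2]),
                "angle_transverse_deg": geom.angle_transverse,
                "angle_sagittal_deg": geom.angle_sagittal,
                "angle_coronal_deg": geom.angle_coronal,
                "stimulus_distance_mm": geom.stimulus_distance,
                "n_candidates": cands.n_candidates,
                "n_evaluated": int(pos.candidate_amplitudes.size),
                "excl_inside_skull": cands.excluded["inside_skull"],
                "excl_below_average_radius": cands.excluded["below_average_radius"],
                "excl_contact_clearance": cands.excluded["contact_clearance"],
                "fwhm_length_water_mm": fm_w.fwhm_length,
                "fwhm_width_water_mm": fm_w.fwhm_width,
                "fwhm_offset_water_deg": fm_w.offset_angle,
                "fwhm_length_skull_mm": fm_s.fwhm_length,
                "fwhm_width_skull_mm": fm_s.fwhm_width,
                "fwhm_offset_skull_deg": fm_s.offset_angle,
                "deviation_length_mm": dev.delta_length,
                "deviation_length_pct": dev.delta_length_pct,
                "deviation_width_mm": dev.delta_width,
                "deviation_width_pct": dev.delta_width_pct,
                "deviation_offset_deg": dev.delta_offset,
                "amplitude_drop_pct": dev.amplitude_drop_pct,
                "peak_amplitude_pa": fm_s.peak_amplitude,
                "mi": safety.mi,
                "i_sppa_w_cm2": safety.i_sppa,
                "i_spta_mw_cm2": safety.i_spta,
                "fda_mi_ok": safety.fda_mi_ok,
                "fda_isppa_ok": safety.fda_isppa_ok,
                "peak_temperature_c": th_report["peak_temperature_c"],
                "exceeds_42": th_report["exceeds_42"],
                "exceeds_47": th_report["exceeds_47"],
                "exceeds_50": th_report["exceeds_50"],
                "control_group": [
                    {
                        "plane": p.plane, "angle_deg": p.angle,
                        "target_amplitude_pa": p.target_amplitude,
                        "ratio_to_chosen": p.ratio_to_chosen,
                        "shear_wave_caveat": p.shear_wave_caveat,
                    }
                    for p in pos.control_group
                ],
            })
            timings[f"frequency_{f:.0f}_s"] = time.perf_counter() - t_f
            if write_artifacts:
                np.savetxt(
                    outdir / f"candidates_{f:.0f}Hz.csv",
                    np.column_stack([
                        pos.candidate_centers,
                        pos.candidate_distances,
                        pos.candidate_amplitudes,
                    ]),
                    delimiter=",",
                    header="x_mm,y_mm,z_mm,dist_to_target_mm,target_amplitude_pa",
                    comments="",
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    timings["total_s"] = time.perf_counter() - t_start
    report = PlanningReport(
        rows=rows, config_hash=config_hash(cfg), seed=cfg.rp.seed, runtime=timings
    )
    if write_artifacts:
        report.write(outdir)
    return report
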