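"""Radius-positioning (RP) transducer placement.

The RP method screens extracranial transducer-centre candidates for a
single-element focused bowl: a ball of the bowl's radius of curvature is
drawn around the intracranial target, the mean distance from the model
centre to the skull voxels inside that ball defines a minimum-radius rule,
and candidates are the non-skull, extracranial ball voxels beyond that mean
radius with enough clearance from the skull surface to seat the transducer.
Each surviving candidate is then evaluated by simulating a bowl aimed at
the target and recording the steady-state pressure amplitude at the target
voxel; the candidate with peak target pressure wins.

Per-candidate simulations run by default in a 2D plane through the
candidate and the target (the beam plane), extracted from the 3D property
maps by nearest-neighbour sampling; full-3D evaluation is available where
the budget allows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .properties import MediumMaps, PropertyConstants
from .pulse import PulseSequence
from .solver import (
    SimulationGrid,
    SolverInstabilityError,
    SourceGeometry,
    TransducerSpec,
    amplitude_from_trace,
    discretize_bowl,
    make_grid,
    propagate,
)
from .volumes import SkullMask, cavity_mask

__all__ = [
    "TargetSpec",
    "CandidateMatrix",
    "ControlPose",
    "PositioningResult",
    "NoReachablePlacementError",
    "model_center",
    "candidate_matrix",
    "control_group_placement",
    "extract_beam_plane",
    "evaluate_pose",
    "position_transducer",
]


class NoReachablePlacementError(RuntimeError):
    """The skull is nowhere within one ROC of the target: no placement exists."""


@dataclass
class TargetSpec:
    """Intracranial target point (tumour centre), world mm."""

    point: tuple[float, float, float]
    label: str = "target"

    def verify_intracranial(self, mask: SkullMask) -> None:
        """Check by flood fill that the point lies inside the skull cavity."""
        cav = cavity_mask(mask)
        idx = np.round(mask.world_to_voxel(self.point)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
            raise ValueError(f"target {self.point} outside the volume")
        if not cav[tuple(idx)]:
            raise ValueError(f"target {self.point} is not intracranial")


@dataclass
class CandidateMatrix:
    """RP candidate centres with screening bookkeeping."""

    candidates: np.ndarray  # (n, 3) world mm
    distances_to_target: np.ndarray  # (n,) mm
    model_center: np.ndarray  # world mm
    mean_center_to_shell_distance: float  # mm
    excluded: dict  # reason -> count
    ball_radius: float  # mm
    clearance: float  # mm

    @property
    def n_candidates(self) -> int:
        return int(self.candidates.shape[0])


@dataclass
class ControlPose:
    plane: str  # "transverse" | "coronal"
    angle: float  # degrees from the coronal (+y) axis
    center: np.ndarray  # world mm
    shear_wave_caveat: bool = False  # incidence beyond 45 deg
    target_amplitude: float = float("nan")
    ratio_to_chosen: float = float("nan")


@dataclass
class PositioningResult:
    chosen_center: np.ndarray  # world mm
    chosen_amplitude: float  # Pa at the target voxel
    candidate_centers: np.ndarray  # (n, 3) evaluated candidates
    candidate_amplitudes: np.ndarray  # (n,)
    control_group: list  # list[ControlPose]
    candidate_distances: np.ndarray | None = None  # (n,) mm to target
    failures: int = 0  # candidates skipped due to solver errors


def model_center(mask: SkullMask) -> np.ndarray:
    """Midpoint of the skull extent on each coordinate axis, in world mm.

    Defined per axis as (min occupied index + max occupied index) / 2; for
    disjoint components this is the midpoint of the combined bounding
    extent.
    """
    if not mask.data.any():
        raise ValueError("empty skull mask")
    idx = [np.nonzero(mask.data.any(axis=tuple(a for a in range(3) if a != ax)))[0]
           for ax in range(3)]
    mid = np.array([(i[0] + i[-1]) / 2.0 for i in idx])
    return mask.voxel_to_world(mid)


def candidate_matrix(
    mask: SkullMask,
    target: TargetSpec,
    roc: float,
    clearance: float | None = None,
    transducer: TransducerSpec | None = None,
    ball_radius_margin: float = 0.0,
) -> CandidateMatrix:
    """Screen transducer-centre candidates by the RP rules.

    1. Ball: all voxels within ``roc + ball_radius_margin`` of the target.
    2. Shell hits = ball voxels on the skull; their mean distance to the
       model centre sets the minimum-radius rule.
    3. Candidates = ball voxels outside the flood-filled skull volume with
       distance to the model centre above that mean.
    4. Contact clearance: drop candidates closer to the skull surface than
       ``clearance`` (default: the bowl's cap depth, so the shell of the
       transducer cannot intersect bone).

    Exclusion counts for rules 2-4 are reported.  By construction no
    candidate is intracranial or on the skull.
    """
    if roc <= 0:
        raise ValueError("ROC must be positive")
    if clearance is None:
        clearance = (transducer or TransducerSpec(radius_of_curvature=roc)).cap_depth
    target.verify_intracranial(mask)
    spacing = np.asarray(mask.spacing)
    tgt = np.asarray(target.point, dtype=float)
    ball_r = roc + ball_radius_margin

    # bounding box of the ball, clipped to the volume
    lo = np.maximum(0, np.floor(mask.world_to_voxel(tgt - ball_r)).astype(int))
    hi = np.minimum(np.asarray(mask.shape), np.ceil(mask.world_to_voxel(tgt + ball_r)).astype(int) + 1)
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    world = [mask.origin[a] + grids[a] * spacing[a] for a in range(3)]
    dist_target = np.sqrt(sum((world[a] - tgt[a]) ** 2 for a in range(3)))
    in_ball = dist_target <= ball_r

    sub = tuple(slice(lo[a], hi[a]) for a in range(3))
    skull_sub = mask.data[sub]
    shell_hits = in_ball & skull_sub
    if not shell_hits.any():
        raise NoReachablePlacementError(
            f"skull nowhere within {ball_r:.1f} mm of target {tuple(tgt)}"
        )
    mc = model_center(mask)
    dist_center = np.sqrt(sum((world[a] - mc[a]) ** 2 for a in range(3)))
    mean_d = float(np.mean(dist_center[shell_hits]))

    filled = ndimage.binary_fill_holes(mask.data)[sub]
    inside_skull = in_ball & filled & ~skull_sub  # intracranial ball voxels
    n_inside = int(np.count_nonzero(inside_skull | (in_ball & skull_sub)))

    outside = in_ball & ~filled
    beyond_mean = dist_center > mean_d
    n_below = int(np.count_nonzero(outside & ~beyond_mean))
    cand = outside & beyond_mean

    # distance (mm) from every voxel to the nearest skull voxel
    dist_to_skull = ndimage.distance_transform_edt(~mask.data, sampling=spacing)[sub]
    cleared = dist_to_skull >= clearance
    n_contact = int(np.count_nonzero(cand & ~cleared))
    cand &= cleared

    ci = np.nonzero(cand)
    centers = np.stack([world[a][ci] for a in range(3)], axis=1)
    d2t = dist_target[ci]
    order = np.lexsort((ci[2], ci[1], ci[0]))
    centers = centers[order]
    d2t = d2t[order]
    return CandidateMatrix(
        candidates=centers,
        distances_to_target=d2t,
        model_center=mc,
        mean_center_to_shell_distance=mean_d,
        excluded={
            "inside_skull": n_inside,
            "below_average_radius": n_below,
            "contact_clearance": n_contact,
        },
        ball_radius=ball_r,
        clearance=float(clearance),
    )


def control_group_placement(
    target: TargetSpec,
    roc: float,
    angles=(0.0, 30.0, 45.0, 60.0),
    planes=("transverse", "coronal"),
) -> list[ControlPose]:
    """Fixed-angle control placements at distance ROC from the target.

    Each pose tilts the approach direction away from the coronal (+y) axis
    by the given angle, within the transverse (xy) or coronal (yz) plane.
    The 0-degree poses of both planes coincide (the coronal-axis baseline)
    and are emitted once.  Angles beyond 45 degrees carry a caveat: mode
    conversion to shear waves at such oblique skull incidence is neglected
    by the compressional-only propagation model.
    """
    if roc <= 0:
        raise ValueError("ROC must be positive")
    tgt = np.asarray(target.point, dtype=float)
    poses: list[ControlPose] = []
    seen_baseline = False
    for plane in planes:
        for ang in angles:
            if ang == 0.0:
                if seen_baseline:
                    continue
                seen_baseline = True
            rad = np.deg2rad(ang)
            if plane == "transverse":
                direction = np.array([np.sin(rad), np.cos(rad), 0.0])
            elif plane == "coronal":
                direction = np.array([0.0, np.cos(rad), np.sin(rad)])
            else:
                raise ValueError(f"unknown plane {plane!r}")
            poses.append(
                ControlPose(
                    plane=plane,
                    angle=float(ang),
                    center=tgt + roc * direction,
                    shear_wave_caveat=ang > 45.0,
                )
            )
    return poses


def extract_beam_plane(
    medium: MediumMaps,
    apex,
    target,
    roc: float,
    aperture: float,
    spacing: float | None = None,
    pad: float = 12.0,
):
    """Sample the 3D property maps on the 2D plane through apex and target.

    The plane is spanned by the beam direction e1 = (target-apex)/|.| and a
    perpendicular e2 (the normal to e1 closest to the transverse plane);
    properties are sampled nearest-neighbour so the binary skull shell stays
    crisp.  Returns a 2D MediumMaps plus the apex and target positions in
    the plane's own mm coordinates.
    """
    apex = np.asarray(apex, dtype=float)
    target = np.asarray(target, dtype=float)
    e1 = target - apex
    dist = np.linalg.norm(e1)
    if dist < 1e-9:
        raise ValueError("degenerate pose: apex coincides with target")
    e1 = e1 / dist
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(e1, up)) > 0.95:
        up = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, up)
    e2 /= np.linalg.norm(e2)
    if spacing is None:
        spacing = float(min(medium.spacing))
    # plane coordinates: s along e1 (s=0 at apex), t along e2 (t=0 on axis)
    s_min, s_max = -pad, dist + pad
    t_half = aperture / 2 + pad
    s = np.arange(s_min, s_max + spacing / 2, spacing)
    t = np.arange(-t_half, t_half + spacing / 2, spacing)
    pts = (
        apex[None, None, :]
        + s[:, None, None] * e1[None, None, :]
        + t[None, :, None] * e2[None, None, :]
    )
    vox = (pts - np.asarray(medium.origin)) / np.asarray(medium.spacing)
    coords = np.moveaxis(vox, -1, 0)

    def samp(arr, fill):
        return ndimage.map_coordinates(arr, coords, order=0, mode="constant", cval=fill)

    const = PropertyConstants()
    med2d = MediumMaps(
        sound_speed=samp(medium.sound_speed, const.c_water),
        density=samp(medium.density, const.rho_water),
        alpha_coeff=samp(medium.alpha_coeff, const.alpha_water),
        b_over_a=samp(medium.b_over_a, const.b_over_a),
        skull_mask=None,
        spacing=(spacing, spacing),
        origin=(0.0, 0.0),
        power_law_exponent=medium.power_law_exponent,
    )
    apex_2d = np.array([0.0 - s_min, t_half])
    target_2d = np.array([dist - s_min, t_half])
    return med2d, apex_2d, target_2d


def evaluate_pose(
    medium: MediumMaps,
    apex,
    target_point,
    transducer: TransducerSpec,
    drive: PulseSequence,
    mode: str = "2d",
    cfl: float = 0.3,
    pml_width: int = 10,
    settle_periods: float = 40.0,
    measure_periods: float = 10.0,
    spacing: float | None = None,
    return_field: bool = False,
    first_arrival_gate: bool = False,
    gate_periods: float = 5.0,
):
    """Simulate one bowl pose aimed at the target; return the amplitude (Pa)
    at the target voxel (and optionally the full field with its grid).

    With ``first_arrival_gate`` the amplitude map is time-gated to the
    direct focused wavefront (from its water-path arrival at the target,
    for ``gate_periods`` carrier periods) so that reverberation inside the
    closed skull cavity does not contaminate the focal geometry; the
    target amplitude itself is still read from the steady-state trace.
    """
    roc = transducer.radius_of_curvature
    ap = transducer.aperture_diameter
    if mode == "2d":
        med, apex_p, tgt_p = extract_beam_plane(
            medium, apex, target_point, roc, ap, spacing=spacing
        )
    elif mode == "3d":
        med, apex_p, tgt_p = medium, np.asarray(apex, float), np.asarray(
            target_point, float
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sp = float(med.spacing[0])
    grid = SimulationGrid(
        shape=med.sound_speed.shape,
        spacing=sp,
        dt=cfl * sp * 1e-3 / float(np.max(med.sound_speed)),
        cfl=cfl,
        pml_width=(pml_width,) * med.sound_speed.ndim,
        reference_speed=float(np.max(med.sound_speed)),
        origin=(0.0,) * med.sound_speed.ndim if mode == "2d" else tuple(med.origin),
    )
    # the bowl is aimed at the target; its geometric focus sits one ROC from
    # the apex along that axis (the target itself may be slightly nearer)
    axis = tgt_p - apex_p
    axis = axis / np.linalg.norm(axis)
    focus_geo = apex_p + roc * axis
    source = discretize_bowl(transducer, apex_p, focus_geo, grid)
    tgt_vox = tuple(np.round(grid.world_to_voxel(tgt_p)).astype(int))
    gate_start = None
    if first_arrival_gate:
        dist_m = float(np.linalg.norm(tgt_p - apex_p)) * 1e-3
        t_arrival = dist_m / 1482.0  # water-path transit (shell is faster)
        gate_start = t_arrival * drive.fundamental_frequency + 1.0
    field = propagate(
        grid,
        med,
        source,
        drive,
        probes={"target": tgt_vox},
        settle_periods=settle_periods,
        measure_periods=measure_periods,
        gate_start_periods=gate_start,
        gate_periods=gate_periods,
    )
    if first_arrival_gate:
        amp = amplitude_from_trace(
            field.probe_traces["target"], grid.dt,
            drive.fundamental_frequency, measure_periods)
    else:
        amp = float(field.amplitude[tgt_vox])
    if return_field:
        return amp, field, grid, source, med
    return amp


def position_transducer(
    candidates: CandidateMatrix,
    target: TargetSpec,
    transducer: TransducerSpec,
    medium: MediumMaps,
    drive: PulseSequence | None = None,
    mode: str = "2d",
    subsample: int = 1,
    max_candidates: int | None = None,
    seed: int | None = None,
    control_poses: list[ControlPose] | None = None,
    **solver_kwargs,
) -> PositioningResult:
    """Evaluate candidates by simulated target pressure and pick the peak.

    ``subsample`` keeps every k-th candidate (after the deterministic
    lexicographic ordering); ``max_candidates`` caps the count by uniform
    random choice with ``seed``.  Ties on amplitude break by smaller
    distance to target, then lexicographic candidate order.  Solver
    failures skip the candidate with a warning.
    """
    if candidates.n_candidates == 0:
        raise ValueError("candidate list is empty")
    drive = drive or transducer.drive
    centers = candidates.candidates
    dists = candidates.distances_to_target
    keep = np.arange(0, len(centers), max(1, int(subsample)))
    if max_candidates is not None and keep.size > max_candidates:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(keep, size=max_candidates, replace=False))
    amps = np.full(keep.size, -np.inf)
    failures = 0
    for i, ci in enumerate(keep):
        try:
            amps[i] = evaluate_pose(
                medium, centers[ci], target.point, transducer, drive,
                mode=mode, **solver_kwargs,
            )
        except (SolverInstabilityError, ValueError) as exc:
            failures += 1
            warnings.warn(f"candidate {ci} skipped: {exc}", stacklevel=2)
    ok = np.isfinite(amps)
    if not ok.any():
        raise RuntimeError("every candidate simulation failed")
    # argmax with documented tie-breaks: amplitude desc, distance asc, lex index
    order = np.lexsort((keep, dists[keep], -amps))
    best_pos = order[0]
    chosen = centers[keep[best_pos]]
    chosen_amp = float(amps[best_pos])
    controls = list(control_poses) if control_poses is not None else []
    for pose in controls:
        try:
            pose.target_amplitude = evaluate_pose(
                medium, pose.center, target.point, transducer, drive,
                mode=mode, **solver_kwargs,
            )
        except (SolverInstabilityError, ValueError) as exc:
            warnings.warn(f"control pose {pose.plane}/{pose.angle} failed: {exc}",
                          stacklevel=2)
            pose.target_amplitude = float("nan")
        pose.ratio_to_chosen = pose.target_amplitude / chosen_amp
    return PositioningResult(
        chosen_center=chosen,
        chosen_amplitude=chosen_amp,
        candidate_centers=centers[keep],
        candidate_amplitudes=amps,
        candidate_distances=dists[keep],
        control_group=controls,
        failures=failures,
    )
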