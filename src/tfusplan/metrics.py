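"""Focal geometry, beam-path angles and acoustic safety indices.

The focal region is the connected set of voxels whose pressure amplitude,
normalised by its peak, is at least 0.5 (the -6 dB pressure contour, within
which sonication neuromodulation effects are expected).  Its extent along
the beam axis is the focal length, its largest perpendicular extent the
focal width, and the angle between its principal axis and the geometric
beam axis the offset angle.

Beam-path angles are measured between the sonication vector and the three
anatomical planes (transverse / sagittal / coronal, normals z / x / y):
``angle = arcsin(|v . n|)``, so the squared sines sum to one.

Safety indices follow the FDA diagnostic-ultrasound conventions:
MI = p_neg[MPa] / sqrt(f[MHz]); I_SPPA = p^2 / (2 rho c) (plane-wave
pulse-average intensity); I_SPTA = I_SPPA x duty cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BeamGeometry",
    "FocalMetrics",
    "SafetyIndices",
    "DeviationReport",
    "beam_angles",
    "extract_fwhm",
    "deviation_vs_water",
    "safety_indices",
]

PLANE_NORMALS = {
    "transverse": np.array([0.0, 0.0, 1.0]),
    "sagittal": np.array([1.0, 0.0, 0.0]),
    "coronal": np.array([0.0, 1.0, 0.0]),
}

FDA_MI_LIMIT = 1.9
FDA_ISPPA_LIMIT = 190.0  # W/cm^2


@dataclass
class BeamGeometry:
    path_vector: np.ndarray  # unit, transducer centre -> target
    angle_transverse: float  # degrees
    angle_sagittal: float
    angle_coronal: float
    stimulus_distance: float  # mm


@dataclass
class FocalMetrics:
    """Geometry of the half-maximum focal region."""

    fwhm_length: float  # mm along the beam axis
    fwhm_width: float  # mm, max perpendicular extent
    offset_angle: float  # degrees, principal axis vs beam axis
    peak_amplitude: float  # Pa
    degenerate: bool = False  # half-max region touches the domain boundary


@dataclass
class SafetyIndices:
    mi: float
    i_sppa: float  # W/cm^2
    i_spta: float  # mW/cm^2
    fda_mi_ok: bool
    fda_isppa_ok: bool


@dataclass
class DeviationReport:
    """Water-vs-skull focal degradation (positive = smaller/weaker in skull)."""

    delta_length: float  # mm, water - skull
    delta_length_pct: float  # % of water length
    delta_width: float  # mm
    delta_width_pct: float
    delta_offset: float  # degrees, |skull - water|
    amplitude_drop_pct: float  # 100 * (1 - skull_peak / water_peak)


def beam_angles(center, target) -> BeamGeometry:
    """Angles of the sonication path to the three anatomical planes."""
    center = np.asarray(center, dtype=float)
    target = np.asarray(target, dtype=float)
    vec = target - center
    dist = float(np.linalg.norm(vec))
    if dist < 1e-12:
        raise ValueError("zero-length beam vector")
    v = vec / dist
    ang = {
        name: float(np.degrees(np.arcsin(min(1.0, abs(np.dot(v, n))))))
        for name, n in PLANE_NORMALS.items()
    }
    return BeamGeometry(
        path_vector=v,
        angle_transverse=ang["transverse"],
        angle_sagittal=ang["sagittal"],
        angle_coronal=ang["coronal"],
        stimulus_distance=dist,
    )


def _perpendicular_basis(axis: np.ndarray, plane: str | None) -> np.ndarray:
    """In-plane perpendicular to the beam axis used for the width measure."""
    nd = axis.size
    if nd == 2:
        return np.array([-axis[1], axis[0]])
    if plane in PLANE_NORMALS:
        n = PLANE_NORMALS[plane]
        perp = np.cross(n, axis)
        if np.linalg.norm(perp) < 1e-9:  # beam normal to the plane
            perp = np.cross(axis, [1.0, 0.0, 0.0])
    else:
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(axis, helper)) > 0.95:
            helper = np.array([1.0, 0.0, 0.0])
        perp = np.cross(axis, helper)
    return perp / np.linalg.norm(perp)


def extract_fwhm(
    amplitude: np.ndarray,
    beam_axis,
    spacing: float = 1.0,
    plane: str | None = None,
    threshold: float = 0.5,
    focus_hint=None,
    hint_radius_mm: float = 15.0,
) -> FocalMetrics:
    """Measure the half-maximum focal region of an amplitude map.

    ``amplitude`` is a 2D or 3D non-negative field; ``beam_axis`` a unit
    vector of matching dimensionality; ``spacing`` the isotropic voxel size
    in mm.  ``threshold`` defaults to half-maximum pressure (-6 dB); pass
    ``1/sqrt(2)`` for the intensity-based -3 dB pressure contour.  When
    ``plane="transverse"`` (3D fields) the width is measured within that
    anatomical plane.  Invariant to uniform field scaling.

    Transcranial fields carry standing waves and reverberation whose
    amplitude can rival the focal peak; pass the expected focus position
    (voxel coordinates) as ``focus_hint`` to restrict the analysis to the
    ball of ``hint_radius_mm`` around it: the normalising peak is the local
    maximum in that ball and the half-max region is clipped to it.  A
    region touching the ball boundary (the focal contour merging with the
    incident-beam corridor or the reverberant background) sets the
    ``degenerate`` flag, as does touching the domain boundary.
    """
    amp = np.asarray(amplitude, dtype=float)
    clip = None
    if focus_hint is not None:
        hint = np.asarray(focus_hint, dtype=float)
        grids = np.meshgrid(*[np.arange(n) for n in amp.shape], indexing="ij")
        r2 = sum((g - h) ** 2 for g, h in zip(grids, hint)) * spacing**2
        clip = r2 <= hint_radius_mm**2
        local = np.where(clip, amp, -np.inf)
        peak_idx = np.unravel_index(np.argmax(local), amp.shape)
    else:
        peak_idx = np.unravel_index(np.argmax(amp), amp.shape)
    peak = float(amp[peak_idx])
    if not peak > 0:
        raise ValueError("amplitude field has no strict positive maximum")
    axis = np.asarray(beam_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    norm = amp / peak
    region = norm >= threshold
    if clip is not None:
        unclipped = region.copy()
        region &= clip
    labels, _ = ndimage.label(region)
    region = labels == labels[peak_idx]
    degenerate = any(
        region.take(0, axis=a).any() or region.take(-1, axis=a).any()
        for a in range(amp.ndim)
    )
    if clip is not None:
        # did the clip actually cut the connected region?
        edge = region & ~ndimage.binary_erosion(clip)
        degenerate = degenerate or bool((edge & unclipped).any())
    coords = np.stack(np.nonzero(region), axis=1).astype(float) * spacing
    proj_axis = coords @ axis
    length = float(proj_axis.max() - proj_axis.min()) + spacing
    perp = _perpendicular_basis(axis, plane)
    proj_perp = coords @ perp
    width = float(proj_perp.max() - proj_perp.min()) + spacing
    # principal axis of the region (second central moments)
    centred = coords - coords.mean(axis=0)
    if coords.shape[0] > amp.ndim:
        cov = centred.T @ centred / coords.shape[0]
        w, v = np.linalg.eigh(cov)
        principal = v[:, -1]
        offset = float(np.degrees(np.arccos(min(1.0, abs(np.dot(principal, axis))))))
    else:
        offset = 0.0
    return FocalMetrics(
        fwhm_length=length,
        fwhm_width=width,
        offset_angle=offset,
        peak_amplitude=peak,
        degenerate=degenerate,
    )


def deviation_vs_water(
    skull_metrics: FocalMetrics, water_metrics: FocalMetrics
) -> DeviationReport:
    """Focal degradation of the transcranial field against the free-water
    reference at the same pose and grid."""
    if water_metrics.peak_amplitude <= 0:
        raise ValueError("water reference has zero peak amplitude")
    wl, ww = water_metrics.fwhm_length, water_metrics.fwhm_width
    dl = wl - skull_metrics.fwhm_length
    dw = ww - skull_metrics.fwhm_width
    return DeviationReport(
        delta_length=dl,
        delta_length_pct=100.0 * dl / wl if wl else float("nan"),
        delta_width=dw,
        delta_width_pct=100.0 * dw / ww if ww else float("nan"),
        delta_offset=abs(skull_metrics.offset_angle - water_metrics.offset_angle),
        amplitude_drop_pct=100.0
        * (1.0 - skull_metrics.peak_amplitude / water_metrics.peak_amplitude),
    )


def safety_indices(
    peak_negative_pressure: float,
    f: float,
    rho: float = 1000.0,
    c: float = 1482.0,
    duty_cycle: float = 0.06,
    pressure_amplitude: float | None = None,
) -> SafetyIndices:
    """FDA-style indices from in-situ pressure at the focus.

    ``peak_negative_pressure`` in Pa enters the MI; the plane-wave
    intensity uses ``pressure_amplitude`` (defaults to the same value,
    appropriate for a linear steady-state field).
    """
    if f <= 0 or rho <= 0 or c <= 0:
        raise ValueError("frequency, density and sound speed must be positive")
    p_amp = peak_negative_pressure if pressure_amplitude is None else pressure_amplitude
    mi = (peak_negative_pressure / 1e6) / np.sqrt(f / 1e6)
    i_sppa = p_amp**2 / (2 * rho * c) / 1e4  # W/m^2 -> W/cm^2
    i_spta = i_sppa * duty_cycle * 1e3  # mW/cm^2
    return SafetyIndices(
        mi=float(mi),
        i_sppa=float(i_sppa),
        i_spta=float(i_spta),
        fda_mi_ok=bool(mi <= FDA_MI_LIMIT),
        fda_isppa_ok=bool(i_sppa <= FDA_ISPPA_LIMIT),
    )
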