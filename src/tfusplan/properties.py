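"""CT-to-acoustic property mapping for transcranial ultrasound.

Skull acoustic properties are derived from CT Hounsfield units through the
porosity ``psi = 1 - H/1000`` (clamped to [0, 1]): sound speed and density
interpolate linearly between water (psi = 1) and compact bone (psi = 0),
while the power-law attenuation prefactor follows
``alpha0 = alpha_min + (alpha_max - alpha_min) * sqrt(psi)``.

The mapping is applied only inside the binarized skull mask; every other
voxel (brain, CSF, coupling medium) is treated as water.  Attenuation
prefactors are stored in Np/MHz^y/m and scaled to a drive frequency with
``alpha(f) = alpha0 * (f / 1 MHz)^y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .volumes import HUVolume, SkullMask

__all__ = [
    "PropertyConstants",
    "PorosityVolume",
    "MediumMaps",
    "porosity_from_hu",
    "property_maps",
    "attenuation_at_frequency",
]


@dataclass(frozen=True)
class PropertyConstants:
    """Reference acoustic constants for water and compact bone.

    Attenuation prefactors are power-law coefficients at 1 MHz
    (Np/MHz^y/m) with exponent ``power_law_exponent``.
    """

    c_water: float = 1482.0  # m/s
    c_bone: float = 3100.0  # m/s
    rho_water: float = 1000.0  # kg/m^3
    rho_bone: float = 2200.0  # kg/m^3
    alpha_water: float = 3.48e-4  # Np/MHz^y/m
    alpha_min_skull: float = 21.5  # Np/MHz^y/m
    alpha_max_skull: float = 208.9  # Np/MHz^y/m
    b_over_a: float = 5.2  # nonlinearity parameter, uniform
    power_law_exponent: float = 1.51

    def __post_init__(self) -> None:
        if min(self.c_water, self.c_bone, self.rho_water, self.rho_bone) <= 0:
            raise ValueError("speeds and densities must be positive")
        if self.alpha_min_skull > self.alpha_max_skull:
            raise ValueError("alpha_min_skull must not exceed alpha_max_skull")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PorosityVolume:
    """Per-voxel porosity psi in [0, 1] on the source HU grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class MediumMaps:
    """Heterogeneous acoustic property volumes for the wave solver."""

    sound_speed: np.ndarray  # m/s
    density: np.ndarray  # kg/m^3
    alpha_coeff: np.ndarray  # Np/MHz^y/m (power-law prefactor)
    b_over_a: np.ndarray  # dimensionless
    skull_mask: SkullMask | None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    power_law_exponent: float = 1.51

    @property
    def shape(self):
        return self.sound_speed.shape

    @classmethod
    def homogeneous_water(
        cls,
        shape,
        spacing=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
        const: PropertyConstants | None = None,
    ) -> "MediumMaps":
        """A uniform water medium (the skull-free reference)."""
        const = const or PropertyConstants()
        shape = tuple(shape)
        return cls(
            sound_speed=np.full(shape, const.c_water),
            density=np.full(shape, const.rho_water),
            alpha_coeff=np.full(shape, const.alpha_water),
            b_over_a=np.full(shape, const.b_over_a),
            skull_mask=None,
            spacing=tuple(spacing),
            origin=tuple(origin),
            power_law_exponent=const.power_law_exponent,
        )


def porosity_from_hu(hu) -> np.ndarray | float:
    """Porosity psi = clamp(1 - H/1000, 0, 1).

    Dense bone (H >= 1000 HU) saturates at psi = 0 and air (H <= -1000)
    or water at psi = 1 — clamping keeps psi a physical fraction.
    """
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU must be finite")
    psi = np.clip(1.0 - hu / 1000.0, 0.0, 1.0)
    return psi if psi.ndim else float(psi)


def property_maps(
    hu: HUVolume,
    mask: SkullMask,
    const: PropertyConstants | None = None,
) -> MediumMaps:
    """Map a HU volume + skull mask to heterogeneous acoustic property maps.

    Inside the mask the porosity mixing rules apply; outside, voxels carry
    water constants exactly (the attenuation rule evaluated at psi = 1 would
    otherwise assign skull-level absorption to water).
    """
    const = const or PropertyConstants()
    if hu.shape != mask.shape:
        raise ValueError(f"shape mismatch: HU {hu.shape} vs mask {mask.shape}")
    psi = porosity_from_hu(hu.data)
    m = mask.data
    c = np.full(hu.shape, const.c_water)
    rho = np.full(hu.shape, const.rho_water)
    alpha = np.full(hu.shape, const.alpha_water)
    c[m] = const.c_water * psi[m] + const.c_bone * (1.0 - psi[m])
    rho[m] = const.rho_water * psi[m] + const.rho_bone * (1.0 - psi[m])
    alpha[m] = const.alpha_min_skull + (
        const.alpha_max_skull - const.alpha_min_skull
    ) * np.sqrt(psi[m])
    return MediumMaps(
        sound_speed=c,
        density=rho,
        alpha_coeff=alpha,
        b_over_a=np.full(hu.shape, const.b_over_a),
        skull_mask=mask,
        spacing=hu.spacing,
        origin=hu.origin,
        power_law_exponent=const.power_law_exponent,
    )


def attenuation_at_frequency(alpha0, f: float, y: float = 1.51):
    """Attenuation in Np/m at frequency ``f`` (Hz): alpha0 * (f/1 MHz)^y."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return np.asarray(alpha0) * (f / 1e6) ** y
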