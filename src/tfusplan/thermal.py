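"""Pennes bioheat simulation of sonication-induced heating.

The absorbed acoustic power density closes the loop from the pressure
field: ``Q = alpha(f) * p^2 / (rho c)`` per voxel (plane-wave absorption),
time-averaged over the pulse schedule by the duty cycle.  Temperature then
follows the Pennes equation

    rho C dT/dt = div(k grad T) + Q(t) - w rho C (T - T_a),

stepped with an explicit finite-difference scheme in conservative (flux)
form with insulated (zero-flux) boundaries.  Perfusion w defaults to zero.
Individual 200 us bursts are not resolved thermally: diffusion over a
burst period is negligible, so heating within each sonication window is
applied as the duty-scaled average — the schedule windows themselves (the
500 ms sonication on/off pattern) are resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .properties import MediumMaps, attenuation_at_frequency

__all__ = [
    "ThermalProperties",
    "HeatSource",
    "ThermalResult",
    "heat_deposition",
    "solve_pennes",
    "thermal_safety_report",
]

SKULL_SPECIFIC_HEAT = 1300.0  # J/kg/K
SKULL_CONDUCTIVITY = 1.16  # W/m/K (printed as 1.16e-2 W/cm/degC)
WATER_SPECIFIC_HEAT = 4178.0  # J/kg/K
WATER_CONDUCTIVITY = 0.54  # W/m/K
DEFAULT_BASELINE_TEMPERATURE = 38.5  # degC, intracranial baseline


@dataclass
class ThermalProperties:
    """Per-voxel thermal maps sharing the acoustic grid."""

    specific_heat: np.ndarray  # J/kg/K
    conductivity: np.ndarray  # W/m/K
    density: np.ndarray  # kg/m^3
    perfusion_rate: np.ndarray | float = 0.0  # 1/s
    spacing: float = 1.0  # mm, isotropic

    def __post_init__(self) -> None:
        if np.any(self.specific_heat <= 0) or np.any(self.density <= 0):
            raise ValueError("specific heat and density must be positive")
        if np.any(np.asarray(self.conductivity) < 0):
            raise ValueError("negative thermal conductivity")

    @classmethod
    def from_medium(
        cls,
        medium: MediumMaps,
        skull_mask: np.ndarray | None = None,
        c_skull: float = SKULL_SPECIFIC_HEAT,
        k_skull: float = SKULL_CONDUCTIVITY,
        c_water: float = WATER_SPECIFIC_HEAT,
        k_water: float = WATER_CONDUCTIVITY,
    ) -> "ThermalProperties":
        """Water/skull two-phase thermal maps on the acoustic medium's grid.

        ``skull_mask`` defaults to the medium's own mask; with neither, the
        whole domain is water-equivalent.
        """
        shape = medium.sound_speed.shape
        if skull_mask is None and medium.skull_mask is not None:
            skull_mask = medium.skull_mask.data
        heat = np.full(shape, c_water)
        cond = np.full(shape, k_water)
        if skull_mask is not None:
            heat[skull_mask] = c_skull
            cond[skull_mask] = k_skull
        return cls(
            specific_heat=heat,
            conductivity=cond,
            density=np.asarray(medium.density, dtype=float),
            spacing=float(medium.spacing[0]),
        )


@dataclass
class HeatSource:
    """Volumetric deposition with its on/off sonication schedule."""

    q: np.ndarray  # W/m^3, already duty-averaged within bursts
    schedule: list  # [(start_s, stop_s), ...] sonication windows
    duty_cycle: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.q < 0):
            raise ValueError("heat deposition must be non-negative")
        prev_stop = -np.inf
        for start, stop in self.schedule:
            if start < prev_stop or stop <= start:
                raise ValueError("schedule windows must be ordered, non-overlapping")
            prev_stop = stop

    def active(self, t: float) -> bool:
        return any(start <= t < stop for start, stop in self.schedule)


@dataclass
class ThermalResult:
    temperature: np.ndarray  # final field, degC
    peak_temperature: float  # degC over all steps and voxels
    peak_location: tuple  # voxel index
    time_of_peak: float  # s
    min_temperature: float  # degC over all steps (max-principle diagnostic)
    baseline: float  # degC
    snapshots: dict  # time_s -> field copy
    times: np.ndarray  # s
    peak_history: np.ndarray  # degC per step


def heat_deposition(
    amplitude: np.ndarray,
    medium: MediumMaps,
    f: float,
    duty_cycle: float = 1.0,
    schedule=None,
) -> HeatSource:
    """Absorbed power density from a steady-state pressure amplitude map.

    Q = alpha(f) * p^2 / (rho c) with alpha in Np/m at the drive frequency,
    scaled by the within-burst duty cycle for time-averaged heating.
    """
    amp = np.asarray(amplitude, dtype=float)
    if amp.shape != medium.sound_speed.shape:
        raise ValueError(
            f"amplitude shape {amp.shape} does not match medium "
            f"{medium.sound_speed.shape}"
        )
    alpha = attenuation_at_frequency(
        medium.alpha_coeff, f, medium.power_law_exponent
    )
    q = alpha * amp**2 / (medium.density * medium.sound_speed) * duty_cycle
    return HeatSource(
        q=q,
        schedule=list(schedule) if schedule is not None else [(0.0, np.inf)],
        duty_cycle=duty_cycle,
    )


def _divergence_k_grad(temp: np.ndarray, cond: np.ndarray, dx: float) -> np.ndarray:
    """div(k grad T) in conservative flux form with zero-flux boundaries."""
    out = np.zeros_like(temp)
    for a in range(temp.ndim):
        sl_lo = [slice(None)] * temp.ndim
        sl_hi = [slice(None)] * temp.ndim
        sl_lo[a] = slice(None, -1)
        sl_hi[a] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        k_face = 0.5 * (cond[sl_lo] + cond[sl_hi])
        flux = k_face * (temp[sl_hi] - temp[sl_lo]) / dx  # W/m^2 at interior faces
        out[sl_lo] += flux / dx
        out[sl_hi] -= flux / dx
    return out


def solve_pennes(
    thermal: ThermalProperties,
    source: HeatSource,
    duration: float,
    t0: float = DEFAULT_BASELINE_TEMPERATURE,
    dt: float | None = None,
    arterial_temperature: float | None = None,
    snapshot_times=(),
    initial_temperature: np.ndarray | None = None,
) -> ThermalResult:
    """Step the Pennes equation explicitly over the sonication schedule.

    ``dt`` defaults to 80% of the diffusion stability bound
    ``dx^2 / (2 * ndim * max(D))``; supplying a larger value raises.  The
    peak temperature is tracked at every step (real-time monitoring), not
    just at snapshot times.
    """
    dx = thermal.spacing * 1e-3  # m
    rho_c = thermal.density * thermal.specific_heat
    diffusivity = np.max(thermal.conductivity / rho_c)
    nd = thermal.specific_heat.ndim
    dt_bound = dx**2 / (2 * nd * diffusivity) if diffusivity > 0 else np.inf
    if dt is None:
        dt = min(0.8 * dt_bound, duration / 10)
    elif dt > dt_bound:
        raise ValueError(
            f"dt={dt:.3e} s violates the explicit stability bound "
            f"{dt_bound:.3e} s"
        )
    t_art = t0 if arterial_temperature is None else arterial_temperature
    perf = np.asarray(thermal.perfusion_rate)
    temp = (
        np.full(thermal.specific_heat.shape, float(t0))
        if initial_temperature is None
        else np.array(initial_temperature, dtype=float)
    )
    n_steps = int(np.ceil(duration / dt))
    snapshot_times = sorted(snapshot_times)
    snaps: dict = {}
    peak = float(temp.max())
    peak_loc = np.unravel_index(np.argmax(temp), temp.shape)
    t_peak = 0.0
    tmin = float(temp.min())
    times = np.arange(1, n_steps + 1) * dt
    peak_hist = np.zeros(n_steps)
    snap_i = 0
    for i in range(n_steps):
        t = i * dt
        rate = _divergence_k_grad(temp, thermal.conductivity, dx)
        if source.active(t):
            rate = rate + source.q
        if np.any(perf > 0):
            rate = rate - perf * rho_c * (temp - t_art)
        temp = temp + dt * rate / rho_c
        cur_peak = float(temp.max())
        peak_hist[i] = cur_peak
        if cur_peak > peak:
            peak = cur_peak
            peak_loc = np.unravel_index(np.argmax(temp), temp.shape)
            t_peak = t + dt
        tmin = min(tmin, float(temp.min()))
        while snap_i < len(snapshot_times) and snapshot_times[snap_i] <= t + dt:
            snaps[snapshot_times[snap_i]] = temp.copy()
            snap_i += 1
    return ThermalResult(
        temperature=temp,
        peak_temperature=peak,
        peak_location=peak_loc,
        time_of_peak=t_peak,
        min_temperature=tmin,
        baseline=float(t0),
        snapshots=snaps,
        times=times,
        peak_history=peak_hist,
    )


#: literature tissue-damage temperature thresholds, degC
DENATURATION_C = 42.0
BONE_NECROSIS_C = 47.0
NECROSIS_C = 50.0


def thermal_safety_report(result: ThermalResult) -> dict:
    """Flag the peak temperature against tissue-damage thresholds:
    denaturation begins at 42 degC, cancellous bone necrosis at 47 degC,
    general necrosis at 50 degC."""
    peak = result.peak_temperature
    return {
        "peak_temperature_c": peak,
        "exceeds_42": bool(peak > DENATURATION_C),
        "exceeds_47": bool(peak > BONE_NECROSIS_C),
        "exceeds_50": bool(peak > NECROSIS_C),
    }
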