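"""Planning configuration: defaults, unit parsing, validation, YAML IO.

Quantities may be given as numbers (SI: Hz, s, Pa; geometry in mm) or as
strings with units ("500 kHz", "200 us", "1 MPa", "30 mm"); validation
normalises everything to the numeric form.
"""

from __future__ import annotations

import dataclasses
import hashlib
import re
from dataclasses import dataclass, field, asdict

import yaml

from .pulse import PulseSequence
from .solver import TransducerSpec
from .volumes import PhantomSpec, DEFAULT_HU_THRESHOLD

__all__ = ["PlanningConfig", "validate_config", "load_config", "save_config",
           "parse_quantity", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration errors."""


_UNIT_SCALE = {
    "hz": 1.0, "khz": 1e3, "mhz": 1e6,
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6,
    "pa": 1.0, "kpa": 1e3, "mpa": 1e6,
    "mm": 1.0, "cm": 10.0, "m": 1000.0,  # geometry stays in mm
    "%": 0.01,
}


def parse_quantity(value, kind: str | None = None) -> float:
    """Parse "500 kHz" / "200 us" / "1 MPa" / "30 mm" into the package's
    working units (Hz, s, Pa, mm).  Plain numbers pass through."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([a-zA-Z%µ]+)\s*", str(value))
    if not m:
        raise ConfigError(f"cannot parse quantity {value!r}")
    num, unit = float(m.group(1)), m.group(2).lower()
    if unit not in _UNIT_SCALE:
        raise ConfigError(f"unknown unit {m.group(2)!r} in {value!r}")
    return num * _UNIT_SCALE[unit]


@dataclass
class SolverSettings:
    cfl: float = 0.3
    power_law_exponent: float = 1.51
    pml_width: int = 10
    mode: str = "2d"  # "2d" | "3d"
    settle_periods: float = 40.0
    measure_periods: float = 10.0
    spacing: float = 1.0  # mm
    max_3d_grid: int = 128  # guard per axis for opt-in 3D runs


@dataclass
class RPSettings:
    ball_radius_margin: float = 0.0  # mm beyond the ROC
    clearance: float | None = None  # mm; None -> bowl cap depth
    subsample: int = 1
    max_candidates: int | None = None
    seed: int = 0


@dataclass
class ThermalSettings:
    baseline_temperature: float = 38.5  # degC
    duration: float = 2.0  # s simulated (sonication window + cool-down)
    dt: float | None = None  # s; None -> stability-bound default
    scheme: str = "explicit"


@dataclass
class PlanningConfig:
    """Full end-to-end planning configuration with study defaults."""

    phantom: PhantomSpec | None = None
    input_nifti: str | None = None
    hu_threshold: float = DEFAULT_HU_THRESHOLD
    resample_spacing: float = 1.0  # mm
    frequencies: list = field(default_factory=lambda: [250e3, 500e3, 690e3, 1100e3])
    transducer: TransducerSpec = field(default_factory=TransducerSpec)
    pulse: PulseSequence = field(default_factory=PulseSequence)
    solver: SolverSettings = field(default_factory=SolverSettings)
    rp: RPSettings = field(default_factory=RPSettings)
    thermal: ThermalSettings = field(default_factory=ThermalSettings)
    control_angles: list = field(default_factory=lambda: [0.0, 30.0, 45.0, 60.0])
    control_planes: list = field(default_factory=lambda: ["transverse", "coronal"])
    target_point: tuple | None = None  # defaults to the phantom's target
    output_dir: str = "planning_output"


def validate_config(config: PlanningConfig) -> PlanningConfig:
    """Normalise units and check ranges; raises ConfigError with every
    problem found."""
    errors: list[str] = []
    cfg = dataclasses.replace(config)
    cfg.frequencies = [parse_quantity(f) for f in cfg.frequencies]
    if not cfg.frequencies:
        errors.append("frequency list is empty")
    if any(f <= 0 for f in cfg.frequencies):
        errors.append("frequencies must be positive")
    if not (0 < cfg.solver.cfl <= 1):
        errors.append(
            f"cfl={cfg.solver.cfl} violates the stability bound 0 < CFL <= 1"
        )
    if cfg.solver.mode not in ("2d", "3d"):
        errors.append(f"solver mode must be '2d' or '3d', got {cfg.solver.mode!r}")
    if cfg.resample_spacing <= 0:
        errors.append("resample spacing must be positive")
    if cfg.phantom is None and cfg.input_nifti is None:
        errors.append("either a phantom spec or an input NIfTI path is required")
    try:
        cfg.pulse = dataclasses.replace(
            cfg.pulse,
            fundamental_frequency=parse_quantity(cfg.pulse.fundamental_frequency),
            tone_burst_duration=parse_quantity(cfg.pulse.tone_burst_duration),
            pulse_repetition_frequency=parse_quantity(
                cfg.pulse.pulse_repetition_frequency
            ),
            sonication_duration=parse_quantity(cfg.pulse.sonication_duration),
            source_pressure=parse_quantity(cfg.pulse.source_pressure),
        )
        cfg.pulse.validate()
    except (ValueError, ConfigError) as exc:
        errors.append(f"pulse sequence: {exc}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _to_plain(cfg: PlanningConfig) -> dict:
    d = asdict(cfg)
    if d.get("phantom") and callable(d["phantom"].get("shell_hu")):
        raise ConfigError("callable HU profiles cannot be serialised")
    return d


def save_config(cfg: PlanningConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=True)


def load_config(path) -> PlanningConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return config_from_dict(d)


def config_from_dict(d: dict) -> PlanningConfig:
    d = dict(d or {})
    kwargs: dict = {}
    if d.get("phantom"):
        ph = dict(d["phantom"])
        for key in ("center", "target_point", "domain_extent", "origin"):
            if key in ph:
                ph[key] = tuple(ph[key])
        kwargs["phantom"] = PhantomSpec(**ph)
    for key, cls in (
        ("transducer", TransducerSpec),
        ("pulse", PulseSequence),
        ("solver", SolverSettings),
        ("rp", RPSettings),
        ("thermal", ThermalSettings),
    ):
        if key in d and d[key] is not None:
            sub = dict(d[key])
            if key == "transducer":
                sub.pop("drive", None)
            kwargs[key] = cls(**sub)
    for key in (
        "input_nifti", "hu_threshold", "resample_spacing", "frequencies",
        "control_angles", "control_planes", "target_point", "output_dir",
    ):
        if key in d and d[key] is not None:
            kwargs[key] = tuple(d[key]) if key == "target_point" else d[key]
    return PlanningConfig(**kwargs)


def config_hash(cfg: PlanningConfig) -> str:
    """Stable hash of the normalised configuration (traceability key).

    The output directory is excluded: it does not influence the result.
    """
    plain = _to_plain(cfg)
    plain.pop("output_dir", None)
    blob = yaml.safe_dump(plain, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
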