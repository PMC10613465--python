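"""Pulsed sonication schedules.

A neuromodulation sonication is a train of tone bursts: a carrier at the
fundamental frequency FF gated into bursts of duration TBD repeating at the
pulse repetition frequency PRF over a total sonication duration SD.  The
duty cycle is TBD*PRF.  The default schedule (500 kHz carrier, 200 us
bursts, 300 Hz PRF, 500 ms sonication, 1 MPa drive) has a 6% duty cycle and
150 pulse-repetition periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PulseSequence", "Timing", "derive_timing", "synthesize_waveform"]


@dataclass(frozen=True)
class PulseSequence:
    """Tone-burst drive: carrier frequency, burst gating and amplitude."""

    fundamental_frequency: float = 500e3  # Hz
    tone_burst_duration: float = 200e-6  # s
    pulse_repetition_frequency: float = 300.0  # Hz
    sonication_duration: float = 0.5  # s
    source_pressure: float = 1e6  # Pa

    def validate(self) -> None:
        ff, tbd = self.fundamental_frequency, self.tone_burst_duration
        prf, sd = self.pulse_repetition_frequency, self.sonication_duration
        errors = []
        if not (0 < tbd <= 1 / prf):
            errors.append(f"need 0 < TBD <= 1/PRF ({tbd} vs {1 / prf})")
        if sd < 1 / prf:
            errors.append("sonication duration shorter than one pulse period")
        if ff * tbd < 1:
            errors.append("burst shorter than one carrier cycle")
        if self.source_pressure <= 0:
            errors.append("source pressure must be positive")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass(frozen=True)
class Timing:
    duty_cycle: float  # fraction
    n_bursts: int  # pulse-repetition periods within SD
    cycles_per_burst: int  # carrier cycles per tone burst


def derive_timing(seq: PulseSequence) -> Timing:
    """Duty cycle, burst count and carrier cycles per burst."""
    seq.validate()
    return Timing(
        duty_cycle=seq.tone_burst_duration * seq.pulse_repetition_frequency,
        n_bursts=int(np.floor(seq.sonication_duration * seq.pulse_repetition_frequency)),
        cycles_per_burst=int(round(seq.fundamental_frequency * seq.tone_burst_duration)),
    )


def synthesize_waveform(seq: PulseSequence, dt: float, duration: float) -> np.ndarray:
    """Sample the gated drive signal: sin at FF inside rectangular burst
    windows of width TBD at period 1/PRF, zero between bursts."""
    seq.validate()
    if dt >= 1 / (2 * seq.fundamental_frequency):
        raise ValueError("dt violates the Nyquist limit for the carrier")
    if duration > seq.sonication_duration + 1e-12:
        raise ValueError("duration exceeds the sonication duration")
    t = np.arange(int(round(duration / dt))) * dt
    phase_in_period = np.mod(t, 1.0 / seq.pulse_repetition_frequency)
    envelope = phase_in_period < seq.tone_burst_duration
    return (
        seq.source_pressure
        * envelope
        * np.sin(2 * np.pi * seq.fundamental_frequency * t)
    )
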