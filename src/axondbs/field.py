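"""Extracellular point-source field and stimulus waveform programs.

A monopolar point source in an infinite homogeneous isotropic medium
(quasi-static): phi = rho * I / (4 pi r). Stimulus programs are trains of
monophasic cathodic rectangular pulses or sinusoids; amplitudes are peak
values and cathodic currents are negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FieldModel",
    "StimulusProgram",
    "point_source_potential",
    "waveform_sample",
    "step_average_current",
    "apply_extracellular",
]


@dataclass(frozen=True)
class FieldModel:
    """Point-source volume conductor. Resistivity in ohm-cm, position in mm."""

    resistivity_ohm_cm: float = 500.0
    source_position_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.resistivity_ohm_cm <= 0:
            raise ValueError("resistivity must be positive")


Waveform = Literal["monophasic_cathodic_pulse", "sinusoid"]


@dataclass(frozen=True)
class StimulusProgram:
    """Extracellular stimulus waveform description.

    ``amplitude_ma`` is the peak current magnitude in mA; cathodic pulses
    are delivered as -|amplitude|. The sinusoid is zero-phase,
    amplitude*sin(2 pi f t).
    """

    waveform: Waveform = "monophasic_cathodic_pulse"
    frequency_hz: float = 100.0
    amplitude_ma: float = 1.0
    pulse_width_us: float = 90.0
    epoch_ms: float = 1000.0

    def __post_init__(self):
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if not math.isfinite(self.amplitude_ma):
            raise ValueError("amplitude must be finite")
        if self.waveform == "monophasic_cathodic_pulse":
            if self.pulse_width_us * 1e-3 >= self.period_ms:
                raise ValueError("pulse width must be shorter than the period")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    def with_amplitude(self, amplitude_ma: float) -> "StimulusProgram":
        return StimulusProgram(self.waveform, self.frequency_hz,
                               amplitude_ma, self.pulse_width_us,
                               self.epoch_ms)


def point_source_potential(current_ma, distance_mm, resistivity_ohm_cm=500.0):
    """Potential (V) of a point source: rho*I/(4 pi r). Arrays broadcast."""
    r = np.asarray(distance_mm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive (point-source singularity)")
    rho_ohm_m = resistivity_ohm_cm * 0.01
    phi = rho_ohm_m * np.asarray(current_ma, dtype=float) / (4.0 * np.pi * r)
    return phi if phi.ndim else float(phi)


def waveform_sample(program: StimulusProgram, t_ms):
    """Instantaneous stimulus current (mA) at time(s) t_ms."""
    t = np.asarray(t_ms, dtype=float)
    if program.waveform == "sinusoid":
        out = program.amplitude_ma * np.sin(
            2.0 * np.pi * program.frequency_hz * t * 1e-3)
    else:
        phase = np.mod(t, program.period_ms)
        out = np.where(phase < program.pulse_width_us * 1e-3,
                       -abs(program.amplitude_ma), 0.0)
    return out if out.ndim else float(out)


def _pulse_on_time(t_ms: np.ndarray, period: float, pw: float) -> np.ndarray:
    """Cumulative pulse on-time in [0, t] for a pulse train starting at 0."""
    k = np.floor(t_ms / period)
    return k * pw + np.minimum(t_ms - k * period, pw)


def step_average_current(program: StimulusProgram, dt_ms: float,
                         n_steps: int) -> np.ndarray:
    """Charge-exact per-step average current (mA) on a uniform time grid.

    Averaging the waveform over each [k*dt, (k+1)*dt) interval preserves
    the delivered charge at any time step, which keeps coarse-step
    integration faithful for 90 us pulses.
    """
    edges = np.arange(n_steps + 1) * dt_ms
    if program.waveform == "sinusoid":
        w = 2.0 * np.pi * program.frequency_hz * 1e-3
        integral = -program.amplitude_ma * np.cos(w * edges) / w
    else:
        pw = program.pulse_width_us * 1e-3
        on = _pulse_on_time(edges, program.period_ms, pw)
        integral = -abs(program.amplitude_ma) * on
    return np.diff(integral) / dt_ms


def apply_extracellular(field_model: FieldModel, program: StimulusProgram,
                        distances_mm: np.ndarray, t_ms) -> np.ndarray:
    """Per-compartment extracellular potential (mV) at time t_ms.

    ``distances_mm`` is the per-compartment source distance profile (see
    population.fiber_distance_profile). Result has shape
    (len(t), n_comp) for array t, else (n_comp,).
    """
    r = np.asarray(distances_mm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("all compartments must be at r > 0 from the source")
    unit_mv = point_source_potential(1.0, r, field_model.resistivity_ohm_cm) * 1e3
    i = waveform_sample(program, t_ms)
    if np.ndim(i) == 0:
        return unit_mv * i
    return np.outer(np.asarray(i), unit_mv)
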