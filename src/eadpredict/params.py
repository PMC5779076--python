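"""Parameter containers shared across the package.

Three small frozen-ish dataclasses describe everything a simulation needs
besides the state vector itself:

* :class:`ModelParameters` — the knobs that drug block and the disease-state
  interventions turn: one dimensionless multiplier per targeted current and
  an additive voltage shift (mV) of the fast-sodium steady-state
  inactivation curves.
* :class:`PacingProtocol` — square-pulse current-clamp stimulation.
* :class:`SolverSettings` — integrator tolerances, output sampling and the
  steady-state stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

#: Currents whose maximal conductance / permeability can be scaled.
SCALABLE_CURRENTS = ("INa", "ICaL", "IKr", "IKs", "IpNa", "Ito", "IK1")


@dataclass
class ModelParameters:
    """Conductance scale factors and the I_Na inactivation shift.

    All scale factors are dimensionless multipliers on the baseline maximal
    conductances (or permeability, for I_CaL); 1.0 reproduces the published
    model.  ``IpNa`` targets the late/persistent sodium current (G_NaL).
    ``shift_INa_inact`` (mV) shifts the fast sodium current's whole
    inactivation process (h-fast, h-slow, j: steady states, time constants
    and CaMK-phosphorylated variants) in the depolarised direction;
    activation (m) is untouched.
    """

    scale_INa: float = 1.0
    scale_ICaL: float = 1.0
    scale_IKr: float = 1.0
    scale_IKs: float = 1.0
    scale_IpNa: float = 1.0
    scale_Ito: float = 1.0
    scale_IK1: float = 1.0
    shift_INa_inact: float = 0.0  # mV

    def __post_init__(self) -> None:
        for name in SCALABLE_CURRENTS:
            value = getattr(self, f"scale_{name}")
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"scale_{name} must be finite and >= 0, got {value}")
        if not np.isfinite(self.shift_INa_inact):
            raise ValueError("shift_INa_inact must be finite")

    def scale(self, current: str) -> float:
        if current not in SCALABLE_CURRENTS:
            raise KeyError(f"unknown current {current!r}; expected one of {SCALABLE_CURRENTS}")
        return getattr(self, f"scale_{current}")

    def with_updates(self, **kwargs) -> "ModelParameters":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    def as_array(self) -> np.ndarray:
        """Pack into the float64 layout the compiled kernels expect."""
        return np.array(
            [
                self.scale_INa,
                self.scale_ICaL,
                self.scale_IKr,
                self.scale_IKs,
                self.scale_IpNa,
                self.scale_Ito,
                self.scale_IK1,
                self.shift_INa_inact,
            ],
            dtype=np.float64,
        )


@dataclass
class PacingProtocol:
    """Square stimulus pulse train.

    Defaults are the slow (bradycardic) protocol used throughout: one 3 ms,
    -25.5 uA/uF pulse every 3 s, starting at the beginning of each pace.
    """

    period: float = 3000.0  # ms
    stimulus_duration: float = 3.0  # ms
    stimulus_amplitude: float = -25.5  # uA/uF
    stimulus_offset: float = 0.0  # ms within each pace

    def __post_init__(self) -> None:
        if not (self.period > self.stimulus_duration > 0):
            raise ValueError("require period > stimulus_duration > 0")
        if not (0 <= self.stimulus_offset < self.period):
            raise ValueError("stimulus_offset must lie within [0, period)")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.stimulus_amplitude, self.stimulus_duration, self.period, self.stimulus_offset],
            dtype=np.float64,
        )

    def stimulus_times(self, duration: float) -> np.ndarray:
        """Onset times (ms) of every stimulus in [0, duration)."""
        starts = np.arange(self.stimulus_offset, duration, self.period)
        return starts


@dataclass
class SolverSettings:
    """Integrator tolerances and steady-state pacing controls."""

    rtol: float = 1e-5
    atol: float = 1e-7
    output_dt: float = 0.1  # ms
    steady_state_norm: float = 1e-6
    max_paces: int = 10000
    max_dt: float = 1.0  # ms, cap on the adaptive internal step

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")


DEFAULT_PACING = PacingProtocol()
DEFAULT_SETTINGS = SolverSettings()
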