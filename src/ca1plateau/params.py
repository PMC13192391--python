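"""Model parameters and instantaneous state for the single-compartment plateau model.

The compartment is an isopotential sphere carrying a passive leak, a
voltage-gated Ca2+ channel (GHK flux with Ca2+-dependent inactivation), an
SK-type Ca2+-activated K+ conductance, a submembrane Ca2+ pool, and a
single-exponential inhibitory synapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any

__all__ = ["ModelParameters", "State", "CurrentBreakdown", "calibrated_parameters"]

FARADAY = 96485.0  # C/mol
GAS_CONSTANT = 8.314  # J/(mol K)


@dataclass(frozen=True)
class ModelParameters:
    """Every constant of the membrane equations, in NEURON-convention units.

    Densities are per cm2 of membrane; voltages in mV; time in ms;
    concentrations in mM.  ``gbar_cal`` carries the permeability-like units
    that make ``gbar_cal * m * h**2 * ghk`` come out in mA/cm2.
    """

    diameter: float = 10.0          # um, sphere diameter
    Cm: float = 1.0                 # uF/cm2
    g_pas: float = 5e-5             # S/cm2 (membrane tau = 20 ms)
    E_pas: float = -65.0            # mV
    gbar_cal: float = 0.0           # permeability-like scale, see class docstring
    tfa: float = 1.0                # dimensionless VGCC tau scale
    ki: float = 1e-3                # mM, half-inactivation [Ca2+]i for h(cai)
    cao: float = 2.0                # mM, extracellular Ca2+
    gbar_kca: float = 0.0           # S/cm2, SK maximal conductance
    E_K: float = -90.0              # mV
    cac: float = 0.025              # mM, SK half-activation [Ca2+]i
    beta_kca: float = 0.03          # 1/ms, SK backward rate
    q10_kca: float = 3.0
    temp_ref_kca: float = 22.0      # degC
    depth: float = 0.1              # um, submembrane shell depth
    tau_r: float = 200.0            # ms, Ca2+ removal time constant
    ca_inf: float = 1e-4            # mM, resting [Ca2+]i
    E_GABA: float = -75.0           # mV
    temperature: float = 32.0       # degC
    dt: float = 0.025               # ms
    F: float = FARADAY
    R: float = GAS_CONSTANT
    ca_drive_clamp: bool = True     # zero the Ca2+ pool drive when I_VGCC is outward

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValueError("diameter must be positive")
        for name in ("cao", "cac", "ki", "tau_r", "depth", "dt", "Cm", "tfa"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        for name in ("g_pas", "gbar_cal", "gbar_kca", "ca_inf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.ca_inf < self.cao):
            raise ValueError("ca_inf must be below cao")

    @property
    def area(self) -> float:
        """Membrane surface area in cm2: pi * d**2 for a sphere of diameter d."""
        d_cm = self.diameter * 1e-4
        return math.pi * d_cm * d_cm

    @property
    def tadj_kca(self) -> float:
        """Temperature adjustment q10**((T - T_ref)/10); divides the SK tau."""
        return self.q10_kca ** ((self.temperature - self.temp_ref_kca) / 10.0)

    @property
    def T_kelvin(self) -> float:
        return self.temperature + 273.15

    def replace(self, **changes: Any) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**d)


# Conductances selected by the grid-search calibration (see ca1plateau.calibrate):
# the feasible set is the region producing repolarizing plateaus of 100-200 ms
# under the standard ignition protocol (10 ms step at twice the minimal
# plateau-evoking amplitude); among feasible cells of the default 20x20 log
# grid this is the one nearest the 150 ms band midpoint that also passes the
# robustness screen (stable rest without SK; all-or-none termination).
CALIBRATED_GBAR_CAL = 0.12877204180706942
CALIBRATED_GBAR_KCA = 5.273301797460712e-06


def calibrated_parameters(**overrides: Any) -> ModelParameters:
    """Parameters with the grid-search-calibrated VGCC and SK conductances."""
    base = dict(gbar_cal=CALIBRATED_GBAR_CAL, gbar_kca=CALIBRATED_GBAR_KCA)
    base.update(overrides)
    return ModelParameters(**base)


@dataclass
class State:
    """Instantaneous dynamical variables."""

    t: float = 0.0        # ms
    V: float = -65.0      # mV
    m_cal: float = 0.0    # VGCC activation gate, in [0, 1]
    m_kca: float = 0.0    # SK activation gate, in [0, 1]
    cai: float = 1e-4     # mM
    g_syn: float = 0.0    # uS, total synaptic conductance

    def __post_init__(self) -> None:
        if not (0.0 <= self.m_cal <= 1.0 and 0.0 <= self.m_kca <= 1.0):
            raise ValueError("gates must lie in [0, 1]")
        if self.cai < 0 or self.g_syn < 0:
            raise ValueError("cai and g_syn must be non-negative")


@dataclass(frozen=True)
class CurrentBreakdown:
    """Per-mechanism current densities, mA/cm2 (outward positive)."""

    I_pas: float
    I_VGCC: float
    I_KCa: float
    I_GABA: float
    I_inj: float
    I_sum: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "I_sum",
            self.I_pas + self.I_VGCC + self.I_KCa + self.I_GABA - self.I_inj,
        )
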