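"""Stimulus protocols: current steps, mock IPSP waveforms, and IPSG events.

A protocol is an ordered set of events on a clock that starts after the model
has settled to rest.  Events render to two sample-aligned arrays: an injected
current density (mA/cm2, inward-positive in the ``I_inj`` convention of the
membrane equation) and a synaptic conductance (uS).  Synaptic conductance is
a closed-form sum of single exponentials, so rendering is exact at any dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence, Union

import numpy as np

from .params import ModelParameters

__all__ = [
    "CurrentStep",
    "MockIPSP",
    "IPSGEvent",
    "StimulusProtocol",
    "build_protocol",
    "step_protocol",
    "timing_sweep_protocols",
]


@dataclass(frozen=True)
class CurrentStep:
    """Rectangular current injection.

    ``amplitude`` is in pA when ``unit == "pA"`` (converted to density via the
    compartment area at render time) or directly in mA/cm2 when
    ``unit == "density"``.  Positive amplitude depolarizes.
    """

    onset: float          # ms
    duration: float       # ms
    amplitude: float
    unit: str = "density"

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("current step needs onset >= 0 and duration > 0")
        if self.unit not in ("pA", "density"):
            raise ValueError(f"unknown amplitude unit {self.unit!r}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def density(self, area_cm2: float) -> float:
        if self.unit == "pA":
            return self.amplitude * 1e-9 / area_cm2  # pA -> mA, over cm2
        return self.amplitude


@dataclass(frozen=True)
class MockIPSP:
    """IPSP-mimicking injected current: instantaneous hyperpolarizing onset
    followed by exponential decay, I(t) = -A exp(-(t - t0)/tau_decay).

    ``amplitude`` (A > 0) is the hyperpolarizing peak, in pA or mA/cm2.
    """

    onset: float                # ms
    amplitude: float            # > 0, hyperpolarizing
    tau_decay: float = 30.0     # ms
    unit: str = "density"

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("mock IPSP onset must be >= 0")
        if self.amplitude < 0:
            raise ValueError("mock IPSP amplitude is a magnitude; must be >= 0")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive")
        if self.unit not in ("pA", "density"):
            raise ValueError(f"unknown amplitude unit {self.unit!r}")

    def density(self, area_cm2: float) -> float:
        if self.unit == "pA":
            return self.amplitude * 1e-9 / area_cm2
        return self.amplitude


@dataclass(frozen=True)
class IPSGEvent:
    """Inhibitory synaptic conductance event: instantaneous rise by ``g_max``
    then exponential decay with ``tau_syn`` (ExpSyn-style)."""

    onset: float        # ms
    g_max: float        # uS
    tau_syn: float      # ms

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("IPSG onset must be >= 0")
        if self.g_max < 0:
            raise ValueError("IPSG amplitude must be >= 0")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")


Event = Union[CurrentStep, MockIPSP, IPSGEvent]


@dataclass(frozen=True)
class StimulusProtocol:
    """Validated, time-ordered event list with a total duration."""

    events: tuple[Event, ...]
    duration: float           # ms of simulated (post-settle) time
    settle: float = 2000.0    # ms of stimulus-free settling before the clock

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.settle < 0:
            raise ValueError("duration must be > 0 and settle >= 0")
        ordered = tuple(sorted(self.events, key=lambda e: e.onset))
        object.__setattr__(self, "events", ordered)
        steps = [e for e in ordered if isinstance(e, CurrentStep)]
        for a, b in zip(steps, steps[1:]):
            if b.onset < a.offset:
                raise ValueError(
                    f"overlapping current steps at {a.onset} and {b.onset} ms"
                )

    @property
    def stim_offset(self) -> float | None:
        """End of the last rectangular step — the plateau-duration reference."""
        offs = [e.offset for e in self.events if isinstance(e, CurrentStep)]
        return max(offs) if offs else None

    @property
    def step_onset(self) -> float | None:
        ons = [e.onset for e in self.events if isinstance(e, CurrentStep)]
        return min(ons) if ons else None

    def with_events(self, *extra: Event) -> "StimulusProtocol":
        return StimulusProtocol(self.events + tuple(extra), self.duration, self.settle)

    def with_ipsg(self, t_from_step_onset: float, g_max: float,
                  tau_syn: float) -> "StimulusProtocol":
        """Add an IPSG event timed relative to plateau initiation (step onset)."""
        t0 = self.step_onset
        if t0 is None:
            raise ValueError("protocol has no current step to time the IPSG against")
        return self.with_events(IPSGEvent(t0 + t_from_step_onset, g_max, tau_syn))

    def render(self, dt: float, area_cm2: float) -> tuple[np.ndarray, np.ndarray]:
        """Sample the protocol: (I_inj density mA/cm2, g_syn uS) on the dt grid."""
        n = int(round(self.duration / dt)) + 1
        t = np.arange(n) * dt
        i_inj = np.zeros(n)
        g_syn = np.zeros(n)
        for ev in self.events:
            if isinstance(ev, CurrentStep):
                mask = (t >= ev.onset) & (t < ev.offset)
                i_inj[mask] += ev.density(area_cm2)
            elif isinstance(ev, MockIPSP):
                mask = t >= ev.onset
                i_inj[mask] += -ev.density(area_cm2) * np.exp(
                    -(t[mask] - ev.onset) / ev.tau_decay
                )
            elif isinstance(ev, IPSGEvent):
                mask = t >= ev.onset
                g_syn[mask] += ev.g_max * np.exp(-(t[mask] - ev.onset) / ev.tau_syn)
        return i_inj, g_syn

    def to_dict(self) -> dict[str, Any]:
        evs = []
        for ev in self.events:
            d = {"kind": _KIND_OF[type(ev)]}
            d.update({k: getattr(ev, k) for k in ev.__dataclass_fields__})
            evs.append(d)
        return {"duration": self.duration, "settle": self.settle, "events": evs}


_KIND_OF = {CurrentStep: "current_step", MockIPSP: "mock_ipsp", IPSGEvent: "ipsg_event"}
_EVENT_TYPES = {v: k for k, v in _KIND_OF.items()}


def build_protocol(spec: Mapping[str, Any]) -> StimulusProtocol:
    """Build a protocol from a plain mapping (the config-file representation).

    ``{"duration": 600, "settle": 2000, "events": [{"kind": "current_step",
    "onset": 10, "duration": 50, "amplitude": 150, "unit": "pA"}, ...]}``
    """
    known_top = {"duration", "settle", "events"}
    unknown = set(spec) - known_top
    if unknown:
        raise KeyError(f"unknown protocol key(s): {sorted(unknown)}")
    events: list[Event] = []
    for ev in spec.get("events", []):
        ev = dict(ev)
        kind = ev.pop("kind", None)
        if kind not in _EVENT_TYPES:
            raise KeyError(f"unknown event kind {kind!r}")
        cls = _EVENT_TYPES[kind]
        known = set(cls.__dataclass_fields__)
        bad = set(ev) - known
        if bad:
            raise KeyError(f"unknown key(s) for {kind}: {sorted(bad)}")
        events.append(cls(**ev))
    return StimulusProtocol(
        tuple(events),
        duration=float(spec.get("duration", 600.0)),
        settle=float(spec.get("settle", 2000.0)),
    )


def step_protocol(amplitude: float, *, onset: float = 10.0, step_ms: float = 50.0,
                  duration: float = 600.0, unit: str = "density",
                  settle: float = 2000.0) -> StimulusProtocol:
    """The standard plateau-evoking protocol: one brief depolarizing step."""
    return StimulusProtocol(
        (CurrentStep(onset, step_ms, amplitude, unit),), duration, settle
    )


def timing_sweep_protocols(base: StimulusProtocol, times: Sequence[float],
                           g_max: float, tau_syn: float) -> list[StimulusProtocol]:
    """Protocols differing only in IPSG onset (times from plateau initiation)."""
    return [base.with_ipsg(t, g_max, tau_syn) for t in times]
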