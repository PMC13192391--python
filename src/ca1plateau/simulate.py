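"""Trace container, resting-state search, ODE integration, and the dt-refinement
integrator check."""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _kernel, mechanisms
from .params import ModelParameters, State
from .protocols import StimulusProtocol

__all__ = [
    "SimulationTrace",
    "SimulationError",
    "NoRestingStateError",
    "initialize_rest",
    "simulate",
    "verify_integrator",
]


class SimulationError(RuntimeError):
    """Numerical blow-up or NaN during integration."""


class NoRestingStateError(RuntimeError):
    """The model failed to settle to a stimulus-free steady state."""


@dataclass
class SimulationTrace:
    """Uniformly sampled state, current decomposition, and gate targets.

    All arrays share one time grid (step ``dt``); the first sample is the
    settled resting state.  Currents are densities in mA/cm2; ``g_syn`` is the
    point synaptic conductance in uS.
    """

    params: ModelParameters
    protocol: StimulusProtocol
    t: np.ndarray
    V: np.ndarray
    m_cal: np.ndarray
    m_kca: np.ndarray
    cai: np.ndarray
    g_syn: np.ndarray
    I_pas: np.ndarray
    I_VGCC: np.ndarray
    I_KCa: np.ndarray
    I_GABA: np.ndarray
    I_inj: np.ndarray
    I_sum: np.ndarray
    m_inf_cal: np.ndarray
    m_inf_kca: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def V_rest(self) -> float:
        return float(self.V[0])

    @property
    def stim_offset(self) -> float | None:
        return self.protocol.stim_offset

    def index_of(self, time_ms: float) -> int:
        return int(round(time_ms / self.dt))

    def dVdt(self) -> np.ndarray:
        """Central-difference dV/dt in mV/ms (one-sided at the ends)."""
        return np.gradient(self.V, self.dt)

    def __len__(self) -> int:
        return self.t.shape[0]


def _kernel_args(p: ModelParameters) -> tuple:
    zfac = 2.0 * p.F * 1e-3 / (p.R * p.T_kelvin)
    return (p.g_pas, p.E_pas, p.gbar_cal, p.tfa, p.ki, p.cao, p.gbar_kca,
            p.E_K, p.cac, p.beta_kca, p.tadj_kca, p.depth, p.tau_r,
            p.ca_inf, p.E_GABA, p.Cm, zfac, p.F, p.ca_drive_clamp)


def _run(p: ModelParameters, s0: State, i_inj: np.ndarray, g_syn: np.ndarray,
         dt: float):
    g_dens = g_syn * 1e-6 / p.area  # uS -> S, over cm2
    status, V, m_cal, m_kca, cai = _kernel.integrate(
        s0.V, s0.m_cal, s0.m_kca, s0.cai, dt, i_inj, g_dens, *_kernel_args(p)
    )
    if status != _kernel.STATUS_OK:
        raise SimulationError(
            f"integration diverged at t = {status * dt:.3f} ms "
            f"(V = {V[status]:.3g} mV); check parameters/stimulus"
        )
    return V, m_cal, m_kca, cai


def _max_abs_derivative(s: State, p: ModelParameters) -> float:
    d = mechanisms.derivatives(s, p)
    return max(abs(d.dV), abs(d.dm_cal), abs(d.dm_kca), abs(d.dcai))


@functools.lru_cache(maxsize=128)
def initialize_rest(p: ModelParameters, *, settle_ms: float = 2000.0,
                    tol: float = 1e-9, max_rounds: int = 10) -> State:
    """Stimulus-free steady state, found by relaxation integration.

    Integrates in rounds of ``settle_ms`` until the largest state derivative
    (native units) falls below ``tol``.  The relaxation starts 20 mV below
    the leak reversal with the Ca2+ pool at its floor, so the trajectory
    approaches the resting state from hyperpolarization: starting at E_pas
    with a fully deinactivated VGCC can transiently ignite the regenerative
    loop and settle onto a depolarized attractor instead of rest.
    """
    v0 = p.E_pas - 20.0
    m0 = mechanisms.cal_rates(v0, p).m_inf
    mk0 = mechanisms.kca_gate(p.ca_inf, p).m_inf
    s = State(t=0.0, V=v0, m_cal=m0, m_kca=mk0, cai=p.ca_inf)
    n = int(round(settle_ms / p.dt)) + 1
    zeros = np.zeros(n)
    for _ in range(max_rounds):
        V, m_cal, m_kca, cai = _run(p, s, zeros, zeros, p.dt)
        s = State(t=0.0, V=float(V[-1]), m_cal=float(np.clip(m_cal[-1], 0, 1)),
                  m_kca=float(np.clip(m_kca[-1], 0, 1)), cai=float(max(cai[-1], 0)))
        if _max_abs_derivative(s, p) < tol:
            return s
    raise NoRestingStateError(
        f"no resting state after {max_rounds * settle_ms:.0f} ms of relaxation "
        f"(residual derivative {_max_abs_derivative(s, p):.3g}); the parameter "
        "set may be spontaneously active"
    )


def _assemble(p: ModelParameters, proto: StimulusProtocol, t, V, m_cal, m_kca,
              cai, g_syn, i_inj) -> SimulationTrace:
    h = mechanisms.h_cal(cai, p)
    ghk = mechanisms.ghk_flux(V, cai, p.cao, p.temperature)
    I_pas = p.g_pas * (V - p.E_pas)
    I_vgcc = p.gbar_cal * m_cal * h * h * ghk
    I_kca = p.gbar_kca * m_kca ** 3 * (V - p.E_K)
    I_gaba = g_syn * 1e-6 * (V - p.E_GABA) / p.area
    I_sum = I_pas + I_vgcc + I_kca + I_gaba - i_inj
    m_inf_cal = mechanisms.cal_rates(V, p).m_inf
    m_inf_kca = mechanisms.kca_gate(cai, p).m_inf
    return SimulationTrace(
        params=p, protocol=proto, t=t, V=V, m_cal=m_cal, m_kca=m_kca, cai=cai,
        g_syn=g_syn, I_pas=I_pas, I_VGCC=I_vgcc, I_KCa=I_kca, I_GABA=I_gaba,
        I_inj=np.asarray(i_inj, dtype=float), I_sum=I_sum,
        m_inf_cal=m_inf_cal, m_inf_kca=m_inf_kca,
    )


def simulate(p: ModelParameters, proto: StimulusProtocol, *,
             dt: float | None = None) -> SimulationTrace:
    """Integrate the model under a protocol, starting from the settled rest.

    ``dt`` overrides the parameter time step (used by the integrator check).
    """
    dt = p.dt if dt is None else dt
    rest = initialize_rest(p)
    i_inj, g_syn = proto.render(dt, p.area)
    V, m_cal, m_kca, cai = _run(p, rest, i_inj, g_syn, dt)
    t = np.arange(len(V)) * dt
    return _assemble(p, proto, t, V, m_cal, m_kca, cai, g_syn, i_inj)


class IntegratorReport(NamedTuple):
    max_dV: float     # mV
    max_dcai: float   # mM
    dt: float
    dt_ref: float


def verify_integrator(p: ModelParameters, proto: StimulusProtocol, *,
                      refine: int = 100) -> IntegratorReport:
    """Re-run a protocol with the same scheme at dt/``refine`` and report the
    maximum state deviation on the coarse grid."""
    coarse = simulate(p, proto)
    fine = simulate(p, proto, dt=p.dt / refine)
    idx = np.arange(len(coarse)) * refine
    dV = np.max(np.abs(coarse.V - fine.V[idx]))
    dca = np.max(np.abs(coarse.cai - fine.cai[idx]))
    return IntegratorReport(float(dV), float(dca), coarse.dt, fine.dt)
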