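"""Pure mechanism math: gating rates, GHK flux, currents, and state derivatives.

All functions accept scalars or numpy arrays in V/cai and broadcast.  Voltage
in mV, time in ms, concentrations in mM, current densities in mA/cm2
(outward positive).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import CurrentBreakdown, ModelParameters, State

__all__ = [
    "cal_rates",
    "ghk_flux",
    "h_cal",
    "kca_gate",
    "membrane_currents",
    "derivatives",
    "efun",
]

# Removable-singularity guard for efun and the cal alpha rate.
_SERIES_EPS = 1e-4


def efun(z):
    """z / (exp(z) - 1), continued through z = 0 with the series 1 - z/2."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < _SERIES_EPS
    zs = np.where(small, 1.0, z)  # avoid 0/0 in the masked lanes
    out = np.where(small, 1.0 - z / 2.0, zs / np.expm1(zs))
    return out if out.ndim else float(out)


class CalRates(NamedTuple):
    alpha: float   # 1/ms
    beta: float    # 1/ms
    m_inf: float
    tau_m: float   # ms


def cal_rates(V, p: ModelParameters) -> CalRates:
    """Voltage-dependent rates for the VGCC activation gate.

    alpha = 0.055 (-27.01 - V) / (exp((-27.01 - V)/3.8) - 1)
    beta  = 0.94 exp((-63.01 - V)/17)
    with m_inf = alpha/(alpha+beta) and tau_m = 1/(tfa (alpha+beta)).
    The alpha expression has a removable singularity at V = -27.01 mV where
    it equals 0.055 * 3.8.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("cal_rates requires finite V")
    u = -27.01 - V
    # alpha = 0.055 * u / (exp(u/3.8) - 1) = 0.055 * 3.8 * efun(u/3.8)
    alpha = 0.055 * 3.8 * efun(u / 3.8)
    beta = 0.94 * np.exp((-63.01 - V) / 17.0)
    m_inf = alpha / (alpha + beta)
    tau_m = 1.0 / (p.tfa * (alpha + beta))
    if V.ndim == 0:
        return CalRates(float(alpha), float(beta), float(m_inf), float(tau_m))
    return CalRates(alpha, beta, m_inf, tau_m)


def ghk_flux(V, cai, cao: float, T_celsius: float):
    """Goldman-Hodgkin-Katz flux factor for Ca2+ (valence 2).

    ghk = 1e-3 * 2F * (cai * efun(-z) - cao * efun(z)),  z = 2FV*1e-3/(RT)

    Negative (inward) below the Ca2+ Nernst potential when cai << cao, zero
    exactly at the Nernst potential, continuous through V = 0.  The product
    gbar_cal * m * h**2 * ghk is a current density in mA/cm2.
    """
    if cao <= 0:
        raise ValueError("cao must be positive")
    cai = np.asarray(cai, dtype=float)
    if np.any(cai < 0):
        raise ValueError("cai must be non-negative")
    from .params import FARADAY, GAS_CONSTANT

    T = T_celsius + 273.15
    z = 2.0 * FARADAY * np.asarray(V, dtype=float) * 1e-3 / (GAS_CONSTANT * T)
    out = 1e-3 * 2.0 * FARADAY * (cai * efun(-z) - cao * efun(z))
    return out if np.ndim(out) else float(out)


def h_cal(cai, p: ModelParameters):
    """Ca2+-dependent VGCC inactivation factor h = ki/(ki + cai) in (0, 1]."""
    cai = np.asarray(cai, dtype=float)
    if np.any(cai < 0):
        raise ValueError("cai must be non-negative")
    out = p.ki / (p.ki + cai)
    return out if out.ndim else float(out)


class KcaGate(NamedTuple):
    m_inf: float
    tau_m: float  # ms


def kca_gate(cai, p: ModelParameters) -> KcaGate:
    """Ca2+-dependent steady state and time constant of the SK gate.

    m_inf = (cai/cac)**2 / (1 + (cai/cac)**2)
    tau_m = 1 / (beta * (1 + (cai/cac)**2)) / tadj
    """
    cai = np.asarray(cai, dtype=float)
    if np.any(cai < 0):
        raise ValueError("cai must be non-negative")
    car = (cai / p.cac) ** 2
    m_inf = car / (1.0 + car)
    tau_m = 1.0 / (p.beta_kca * (1.0 + car)) / p.tadj_kca
    if cai.ndim == 0:
        return KcaGate(float(m_inf), float(tau_m))
    return KcaGate(m_inf, tau_m)


def membrane_currents(s: State, p: ModelParameters, I_inj: float = 0.0) -> CurrentBreakdown:
    """All current densities at a given state.

    I_pas  = g_pas (V - E_pas)
    I_VGCC = gbar_cal m h(cai)^2 ghk(V, cai, cao)
    I_KCa  = gbar_kca m^3 (V - E_K)
    I_GABA = g_syn (V - E_GABA) / area   (g_syn is a point conductance in uS;
             uS*mV = nA, so the density conversion is 1e-6/area)
    """
    h = h_cal(s.cai, p)
    I_pas = p.g_pas * (s.V - p.E_pas)
    I_vgcc = p.gbar_cal * s.m_cal * h * h * ghk_flux(s.V, s.cai, p.cao, p.temperature)
    I_kca = p.gbar_kca * s.m_kca ** 3 * (s.V - p.E_K)
    I_gaba = s.g_syn * 1e-6 * (s.V - p.E_GABA) / p.area
    return CurrentBreakdown(I_pas=I_pas, I_VGCC=I_vgcc, I_KCa=I_kca,
                            I_GABA=I_gaba, I_inj=I_inj)


class Derivatives(NamedTuple):
    dV: float       # mV/ms
    dm_cal: float   # 1/ms
    dm_kca: float   # 1/ms
    dcai: float     # mM/ms


def derivatives(s: State, p: ModelParameters, I_inj: float = 0.0) -> Derivatives:
    """Time derivatives of (V, m_cal, m_kca, cai).

    Cm dV/dt = -I_sum.  With I in mA/cm2 and Cm in uF/cm2 the ratio I/Cm is
    in (1e-3 A)/(1e-6 F) = 1e3 V/s = 1e3 mV/ms, so numerically
    dV/dt [mV/ms] = -1e3 * I_sum / Cm  (check: 1e-3 mA/cm2 = 1 uA/cm2 over
    1 uF/cm2 gives 1 mV/ms).

    dcai/dt = -1e4/(2 F depth) * I_VGCC + (ca_inf - cai)/tau_r with depth in
    um; the inward-flux drive is clamped at >= 0 when I_VGCC is outward
    (unless the clamp is disabled).
    """
    cur = membrane_currents(s, p, I_inj)
    dV = -1e3 * cur.I_sum / p.Cm
    rc = cal_rates(s.V, p)
    dm_cal = (rc.m_inf - s.m_cal) / rc.tau_m
    gk = kca_gate(s.cai, p)
    dm_kca = (gk.m_inf - s.m_kca) / gk.tau_m
    drive = -1e4 / (2.0 * p.F * p.depth) * cur.I_VGCC
    if p.ca_drive_clamp and drive < 0.0:
        drive = 0.0
    dcai = drive + (p.ca_inf - s.cai) / p.tau_r
    return Derivatives(dV, dm_cal, dm_kca, dcai)
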