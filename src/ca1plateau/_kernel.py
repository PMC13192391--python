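"""Fixed-step integrator kernel (numba-compiled).

Operator-split scheme per step of length dt:
  1. both gates advance by their exact exponential relaxation toward the
     steady state evaluated at the start-of-step (V, cai), with tau frozen;
  2. V and cai advance by an explicit midpoint (RK2) update with the freshly
     advanced gates and the stimulus sample of the step.

The formulas duplicate :mod:`ca1plateau.mechanisms`; the test suite checks
the kernel against those reference functions sample by sample.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = -1  # otherwise the sample index where integration failed


@njit(cache=True)
def _efun(z):
    if abs(z) < 1e-4:
        return 1.0 - z / 2.0
    return z / (np.expm1(z))


@njit(cache=True)
def _dv_dcai(V, cai, m_cal, m_kca, i_inj, g_syn_dens,
             g_pas, E_pas, gbar_cal, ki, cao, gbar_kca, E_K,
             depth, tau_r, ca_inf, E_GABA, Cm, zfac, F, clamp):
    h = ki / (ki + cai)
    z = zfac * V
    ghk = 1e-3 * 2.0 * F * (cai * _efun(-z) - cao * _efun(z))
    i_vgcc = gbar_cal * m_cal * h * h * ghk
    i_sum = (g_pas * (V - E_pas)
             + i_vgcc
             + gbar_kca * m_kca * m_kca * m_kca * (V - E_K)
             + g_syn_dens * (V - E_GABA)
             - i_inj)
    dV = -1e3 * i_sum / Cm
    drive = -1e4 / (2.0 * F * depth) * i_vgcc
    if clamp and drive < 0.0:
        drive = 0.0
    dcai = drive + (ca_inf - cai) / tau_r
    return dV, dcai


@njit(cache=True)
def integrate(V0, m_cal0, m_kca0, cai0, dt, i_inj, g_syn_dens,
              g_pas, E_pas, gbar_cal, tfa, ki, cao, gbar_kca, E_K,
              cac, beta_kca, tadj, depth, tau_r, ca_inf, E_GABA,
              Cm, zfac, F, clamp):
    n = i_inj.shape[0]
    V = np.empty(n)
    m_cal = np.empty(n)
    m_kca = np.empty(n)
    cai = np.empty(n)
    V[0] = V0
    m_cal[0] = m_cal0
    m_kca[0] = m_kca0
    cai[0] = cai0
    status = STATUS_OK
    for k in range(n - 1):
        v = V[k]
        ca = cai[k]
        # VGCC gate: alpha = 0.055*3.8*efun(u/3.8), beta = 0.94*exp((-63.01-v)/17)
        u = -27.01 - v
        a = 0.055 * 3.8 * _efun(u / 3.8)
        b = 0.94 * np.exp((-63.01 - v) / 17.0)
        minf = a / (a + b)
        tau = 1.0 / (tfa * (a + b))
        mc = minf + (m_cal[k] - minf) * np.exp(-dt / tau)
        # SK gate
        car = (ca / cac) * (ca / cac)
        minfk = car / (1.0 + car)
        tauk = 1.0 / (beta_kca * (1.0 + car)) / tadj
        mk = minfk + (m_kca[k] - minfk) * np.exp(-dt / tauk)
        # V, cai step with the advanced gates.  Normally an explicit midpoint
        # (RK2) update; when the linear membrane conductance makes the step
        # stiff (huge synaptic conductances during threshold bracketing) the
        # V update switches to a linearized-implicit form, which is
        # unconditionally stable and accurate exactly where V is pinned to
        # the synaptic reversal anyway.
        g_lin = g_pas + gbar_kca * mk * mk * mk + g_syn_dens[k]
        stiff = dt * 1e3 / Cm * g_lin > 0.5
        dV1, dca1 = _dv_dcai(v, ca, mc, mk, i_inj[k], g_syn_dens[k],
                             g_pas, E_pas, gbar_cal, ki, cao, gbar_kca, E_K,
                             depth, tau_r, ca_inf, E_GABA, Cm, zfac, F, clamp)
        if stiff:
            vn = v + dt * dV1 / (1.0 + dt * 1e3 / Cm * g_lin)
            can = ca + dt * dca1
        else:
            vh = v + 0.5 * dt * dV1
            cah = ca + 0.5 * dt * dca1
            if cah < 0.0:
                cah = 0.0
            dV2, dca2 = _dv_dcai(vh, cah, mc, mk, i_inj[k], g_syn_dens[k],
                                 g_pas, E_pas, gbar_cal, ki, cao, gbar_kca, E_K,
                                 depth, tau_r, ca_inf, E_GABA, Cm, zfac, F, clamp)
            vn = v + dt * dV2
            can = ca + dt * dca2
        if can < 0.0:
            can = 0.0
        if not (np.isfinite(vn) and np.isfinite(can)) or abs(vn) > 200.0:
            status = k + 1
            V[k + 1] = vn
            m_cal[k + 1] = mc
            m_kca[k + 1] = mk
            cai[k + 1] = can
            break
        V[k + 1] = vn
        m_cal[k + 1] = mc
        m_kca[k + 1] = mk
        cai[k + 1] = can
    return status, V, m_cal, m_kca, cai
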