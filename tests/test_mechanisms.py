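"""Unit and property tests for the pure mechanism math."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ca1plateau import mechanisms as mech
from ca1plateau.params import FARADAY, GAS_CONSTANT, ModelParameters, State


@pytest.fixture(scope="module")
def p():
    return ModelParameters(gbar_cal=0.1, gbar_kca=1e-5)


class TestCalRates:
    def test_alpha_at_removable_singularity(self, p):
        # analytic limit of 0.055*u/(exp(u/3.8)-1) as u -> 0 is 0.055*3.8
        r = mech.cal_rates(-27.01, p)
        assert r.alpha == pytest.approx(0.055 * 3.8, rel=1e-10)

    def test_beta_at_its_reference_voltage(self, p):
        assert mech.cal_rates(-63.01, p).beta == pytest.approx(0.94, rel=1e-12)

    def test_alpha_direct_evaluation(self, p):
        # V = -23.21 gives u = -3.8: alpha = 0.055*(-3.8)/(e^-1 - 1)
        expect = 0.055 * (-3.8) / (np.exp(-1.0) - 1.0)
        assert mech.cal_rates(-23.21, p).alpha == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(0.3306, abs=5e-5)

    def test_continuity_through_singularity(self, p):
        lo = mech.cal_rates(-27.01 - 1e-7, p)
        hi = mech.cal_rates(-27.01 + 1e-7, p)
        assert abs(lo.alpha - hi.alpha) < 1e-6

    def test_m_inf_monotone_increasing(self, p):
        v = np.linspace(-100.0, 50.0, 3001)
        m = mech.cal_rates(v, p).m_inf
        assert np.all(np.diff(m) > 0)
        assert np.all((m > 0) & (m < 1))

    def test_tau_scaled_by_tfa(self, p):
        t1 = mech.cal_rates(-40.0, p).tau_m
        t5 = mech.cal_rates(-40.0, p.replace(tfa=5.0)).tau_m
        assert t5 == pytest.approx(t1 / 5.0)

    def test_nonfinite_rejected(self, p):
        with pytest.raises(ValueError):
            mech.cal_rates(np.nan, p)


class TestGhkFlux:
    def test_zero_at_nernst_potential(self):
        cai, cao, T = 1e-4, 2.0, 32.0
        v_nernst = (GAS_CONSTANT * (T + 273.15) / (2 * FARADAY)
                    * np.log(cao / cai) * 1e3)
        assert v_nernst == pytest.approx(130.2, abs=0.2)
        assert mech.ghk_flux(v_nernst, cai, cao, T) == pytest.approx(0.0, abs=1e-9)

    def test_zero_voltage_limit(self):
        # z -> 0: flux = 1e-3 * 2F * (cai - cao)
        expect = 1e-3 * 2 * FARADAY * (1e-4 - 2.0)
        got = mech.ghk_flux(0.0, 1e-4, 2.0, 32.0)
        assert got == pytest.approx(expect, rel=1e-9)
        assert got == pytest.approx(-385.9, abs=0.1)

    def test_continuity_at_zero(self):
        assert abs(mech.ghk_flux(1e-9, 1e-4, 2.0, 32.0)
                   - mech.ghk_flux(0.0, 1e-4, 2.0, 32.0)) < 1e-6

    def test_monotone_in_v_with_unique_zero(self):
        """Brute-force grid scan: the flux increases with V (inward current
        shrinking) and crosses zero exactly once, at the Nernst potential."""
        cai, cao, T = 1e-4, 2.0, 32.0
        v = np.linspace(-100.0, 150.0, 25001)
        f = mech.ghk_flux(v, cai, cao, T)
        assert np.all(np.diff(f) > 0)
        zeros = np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)
        assert len(zeros) == 1
        v_nernst = (GAS_CONSTANT * (T + 273.15) / (2 * FARADAY)
                    * np.log(cao / cai) * 1e3)
        assert abs(v[zeros[0]] - v_nernst) < 0.02

    def test_inward_below_nernst(self):
        assert mech.ghk_flux(-60.0, 1e-4, 2.0, 32.0) < 0

    def test_bad_cao_rejected(self):
        with pytest.raises(ValueError):
            mech.ghk_flux(0.0, 1e-4, 0.0, 32.0)


class TestCaDependentGates:
    def test_h_cal_anchors(self, p):
        assert mech.h_cal(0.0, p) == 1.0
        assert mech.h_cal(p.ki, p) == pytest.approx(0.5)
        assert mech.h_cal(3 * p.ki, p) == pytest.approx(0.25)

    def test_h_cal_strictly_decreasing(self, p):
        cai = np.linspace(0, 0.5, 1000)
        assert np.all(np.diff(mech.h_cal(cai, p)) < 0)

    def test_kca_minf_anchors(self, p):
        assert mech.kca_gate(p.cac, p).m_inf == pytest.approx(0.5)
        assert mech.kca_gate(3 * p.cac, p).m_inf == pytest.approx(0.9)

    def test_kca_tau_with_temperature_adjustment(self):
        # cai = cac doubles the rate; tadj = 3^((32-22)/10) = 3 divides tau
        p = ModelParameters(beta_kca=0.03, temperature=32.0, q10_kca=3.0,
                            temp_ref_kca=22.0)
        tau = mech.kca_gate(p.cac, p).tau_m
        assert tau == pytest.approx(1.0 / (0.03 * 2.0) / 3.0, rel=1e-9)
        assert tau == pytest.approx(5.556, abs=1e-3)

    def test_negative_cai_rejected(self, p):
        with pytest.raises(ValueError):
            mech.h_cal(-1e-6, p)
        with pytest.raises(ValueError):
            mech.kca_gate(-1e-6, p)


class TestCurrentsAndDerivatives:
    def test_all_zero_at_leak_reversal(self, p):
        s = State(V=p.E_pas, m_cal=0.0, m_kca=0.0, cai=0.0, g_syn=0.0)
        cur = mech.membrane_currents(s, p)
        assert cur.I_pas == cur.I_VGCC == cur.I_KCa == cur.I_GABA == 0.0
        assert cur.I_sum == 0.0

    def test_gaba_zero_driving_force(self, p):
        s = State(V=p.E_GABA, g_syn=0.01)
        assert mech.membrane_currents(s, p).I_GABA == 0.0

    def test_kca_direct_evaluation(self):
        p = ModelParameters(gbar_kca=1e-4, E_K=-90.0)
        s = State(V=-10.0, m_kca=0.5)
        # 1e-4 * 0.5^3 * 80 mV
        assert mech.membrane_currents(s, p).I_KCa == pytest.approx(1e-3)

    def test_current_identity_on_random_states(self, p):
        rng = np.random.default_rng(0)
        n = 1_000_000
        V = rng.uniform(-100, 40, n)
        m = rng.uniform(0, 1, n)
        mk = rng.uniform(0, 1, n)
        cai = rng.uniform(0, 0.5, n)
        gs = rng.uniform(0, 0.01, n)
        iinj = rng.uniform(-1e-3, 1e-3, n)
        h = mech.h_cal(cai, p)
        I_pas = p.g_pas * (V - p.E_pas)
        I_vgcc = p.gbar_cal * m * h * h * mech.ghk_flux(V, cai, p.cao, p.temperature)
        I_kca = p.gbar_kca * mk ** 3 * (V - p.E_K)
        I_gaba = gs * 1e-6 * (V - p.E_GABA) / p.area
        I_sum = I_pas + I_vgcc + I_kca + I_gaba - iinj
        # spot-check the scalar path against the vectorized identity
        idx = rng.integers(0, n, 200)
        for i in idx:
            cur = mech.membrane_currents(
                State(V=V[i], m_cal=m[i], m_kca=mk[i], cai=cai[i], g_syn=gs[i]),
                p, iinj[i])
            assert cur.I_sum == pytest.approx(I_sum[i], rel=1e-12, abs=1e-15)
            assert cur.I_sum == (cur.I_pas + cur.I_VGCC + cur.I_KCa
                                 + cur.I_GABA - cur.I_inj)

    def test_derivatives_vanish_at_gate_steady_state(self, p):
        V = -40.0
        r = mech.cal_rates(V, p)
        s = State(V=V, m_cal=r.m_inf, m_kca=0.3, cai=0.05)
        d = mech.derivatives(s, p)
        assert d.dm_cal == pytest.approx(0.0, abs=1e-15)

    def test_ca_removal_only_when_no_influx(self):
        p = ModelParameters(gbar_cal=0.0)
        s = State(V=-65.0, cai=2 * p.ca_inf)
        d = mech.derivatives(s, p)
        assert d.dcai == pytest.approx(-p.ca_inf / p.tau_r, rel=1e-12)

    def test_ca_drive_clamp_switch(self):
        # above the Nernst potential the GHK flux is outward; the clamp
        # zeroes the (unphysical) efflux drive unless disabled
        p = ModelParameters(gbar_cal=0.1)
        s = State(V=135.0, m_cal=1.0, cai=1e-4)
        d_on = mech.derivatives(s, p)
        d_off = mech.derivatives(s, p.replace(ca_drive_clamp=False))
        assert d_on.dcai == pytest.approx((p.ca_inf - s.cai) / p.tau_r)
        assert d_off.dcai < d_on.dcai

    def test_passive_dvdt_unit_chain(self, p):
        # 1e-3 mA/cm2 over 1 uF/cm2 must give 1 mV/ms
        pp = ModelParameters(gbar_cal=0.0, gbar_kca=0.0)
        s = State(V=pp.E_pas + 20.0)  # I_pas = 5e-5 * 20 = 1e-3 mA/cm2
        d = mech.derivatives(s, pp)
        assert d.dV == pytest.approx(-1.0, rel=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(V=st.floats(-90.0, 30.0), cai=st.floats(1e-5, 0.3),
       m0=st.floats(0.0, 1.0), mk0=st.floats(0.0, 1.0))
def test_gates_relax_toward_unit_interval(V, cai, m0, mk0):
    """First-order gate dynamics never push a gate out of [0, 1]."""
    p = ModelParameters(gbar_cal=0.1, gbar_kca=1e-5)
    d = mech.derivatives(State(V=V, m_cal=m0, m_kca=mk0, cai=cai), p)
    if m0 == 0.0:
        assert d.dm_cal >= 0
    if m0 == 1.0:
        assert d.dm_cal <= 0
    if mk0 == 0.0:
        assert d.dm_kca >= 0
    if mk0 == 1.0:
        assert d.dm_kca <= 0
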