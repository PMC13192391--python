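import numpy as np
import pytest

from ca1plateau.calibrate import standard_protocol
from ca1plateau.params import ModelParameters, calibrated_parameters
from ca1plateau.plateau import detect_plateau, find_termination_threshold
from ca1plateau.simulate import simulate


@pytest.fixture(scope="session")
def p_cal():
    """Calibrated parameter set (grid-search output frozen as defaults)."""
    return calibrated_parameters()


@pytest.fixture(scope="session")
def p_passive():
    """Leak-only membrane (both active conductances zero)."""
    return ModelParameters(gbar_cal=0.0, gbar_kca=0.0)


@pytest.fixture(scope="session")
def proto_cal(p_cal):
    """Standard ignition protocol for the calibrated cell."""
    return standard_protocol(p_cal)


@pytest.fixture(scope="session")
def control_trace(p_cal, proto_cal):
    return simulate(p_cal, proto_cal)


@pytest.fixture(scope="session")
def control_metrics(control_trace):
    return detect_plateau(control_trace)


@pytest.fixture(scope="session")
def threshold_50_tau10(p_cal, proto_cal):
    """Bisected IPSG termination threshold at 50 ms onset, tau_syn 10 ms."""
    return find_termination_threshold(p_cal, proto_cal, 50.0, 10.0)


def make_square_trace(p, *, rest=-65.0, level=-10.0, t_on=100.0, t_off=300.0,
                      stim_offset=150.0, duration=900.0, dt=0.1):
    """Hand-built trace: rest, a square depolarization, back to rest.

    The protocol carries a step ending at ``stim_offset`` so the detector
    has its reference marker; voltages are synthetic, not simulated.
    """
    from ca1plateau import mechanisms
    from ca1plateau.protocols import step_protocol
    from ca1plateau.simulate import SimulationTrace

    proto = step_protocol(1e-4, onset=stim_offset - 50.0, step_ms=50.0,
                          duration=duration)
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    V = np.full(n, rest)
    V[(t >= t_on) & (t < t_off)] = level
    z = np.zeros(n)
    return SimulationTrace(
        params=p, protocol=proto, t=t, V=V,
        m_cal=z.copy(), m_kca=z.copy(), cai=np.full(n, p.ca_inf),
        g_syn=z.copy(), I_pas=z.copy(), I_VGCC=z.copy(), I_KCa=z.copy(),
        I_GABA=z.copy(), I_inj=z.copy(), I_sum=z.copy(),
        m_inf_cal=np.asarray(mechanisms.cal_rates(V, p).m_inf),
        m_inf_kca=np.full(n, 0.0),
    )
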