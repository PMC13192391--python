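"""Fixed-point solving, branch tracking, I-V paths, and the dynamic threshold."""

import numpy as np
import pytest

from ca1plateau.params import ModelParameters
from ca1plateau.phase_plane import (estimate_dynamic_threshold,
                                    fixed_points_vs_cai, gate_lag_analysis,
                                    iv_trajectory, solve_fixed_points,
                                    steady_state_current, track_branches)

from conftest import make_square_trace


class TestSteadyStateCurrent:
    def test_passive_zero_at_leak_reversal(self, p_passive):
        assert steady_state_current(p_passive.E_pas, 0.0, p_passive) == 0.0
        roots = solve_fixed_points(0.0, p_passive)
        assert len(roots) == 1
        assert roots[0].V == pytest.approx(p_passive.E_pas, abs=1e-6)
        assert roots[0].stability == "stable"

    def test_conductance_weighted_midpoint(self):
        """SK at cai = cac has m_inf = 0.5; with gbar_kca chosen so the SK
        conductance equals the leak, the unique zero is the conductance-
        weighted midpoint of E_pas = -65 and E_K = -90."""
        p = ModelParameters(gbar_cal=0.0, gbar_kca=5e-5 / 0.5 ** 3)
        roots = solve_fixed_points(p.cac, p)
        assert len(roots) == 1
        assert roots[0].V == pytest.approx(-77.5, abs=1e-4)

    def test_brute_force_oracle_agreement(self, p_cal, control_trace,
                                          control_metrics):
        """Roots from the production solver match an independent 10x-finer
        brute-force scan in count and position (+/- 0.01 mV)."""
        off = control_trace.stim_offset
        for frac in (0.3, 0.6, 0.9):
            cai = float(control_trace.cai[control_trace.index_of(
                off + frac * control_metrics.duration)])
            roots = solve_fixed_points(cai, p_cal, grid_mV=0.01)
            v = np.arange(-100.0, 20.0, 0.001)
            I = steady_state_current(v, cai, p_cal)
            brute = v[np.flatnonzero(np.sign(I[:-1]) * np.sign(I[1:]) < 0)]
            assert len(roots) == len(brute)
            for r, b in zip(roots, brute):
                assert abs(r.V - b) < 0.01

    def test_root_count_parity(self):
        """When the current has opposite signs at the range ends, the root
        count over the range is odd (degree argument), across random
        parameter draws."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(100):
            p = ModelParameters(
                gbar_cal=float(10 ** rng.uniform(-3, 0)),
                gbar_kca=float(10 ** rng.uniform(-6, -3)),
            )
            cai = float(10 ** rng.uniform(-4, -0.5))
            I_lo = steady_state_current(-100.0, cai, p)
            I_hi = steady_state_current(20.0, cai, p)
            if I_lo * I_hi < 0:
                n = len(solve_fixed_points(cai, p, grid_mV=0.05))
                assert n % 2 == 1
                checked += 1
        assert checked > 10

    def test_sign_pattern_around_threshold_root(self, p_cal, control_trace,
                                                control_metrics):
        """Mid-plateau: net inward just above the repelling root, net
        outward just below it."""
        off = control_trace.stim_offset
        cai = float(control_trace.cai[control_trace.index_of(
            off + 0.5 * control_metrics.duration)])
        roots = solve_fixed_points(cai, p_cal, grid_mV=0.05,
                                   v_range=(-100.0, 40.0))
        rep = [r for r in roots
               if r.stability == "repelling"
               and r.V > control_trace.V_rest + 15.0]
        assert rep
        v0 = rep[0].V
        assert steady_state_current(v0 + 1.0, cai, p_cal) < 0
        assert steady_state_current(v0 - 1.0, cai, p_cal) > 0


class TestBranches:
    def test_two_branches_in_plateau_range(self, p_cal, control_trace,
                                           control_metrics):
        fb = track_branches(control_trace, p_cal, stride_ms=5.0,
                            t_start=40.0, t_stop=control_metrics.break_time,
                            grid_mV=0.05)
        for t in (60.0, 90.0, 120.0, 150.0):
            assert fb.count_in_plateau_range(t) == 2

    def test_threshold_branch_drifts_depolarized(self, p_cal, control_trace,
                                                 control_metrics):
        fb = track_branches(control_trace, p_cal, stride_ms=5.0,
                            t_start=40.0, t_stop=control_metrics.break_time,
                            grid_mV=0.05)
        rep = [b for b in fb.plateau_range_branches() if b.label == "repelling"]
        assert rep
        b = max(rep, key=lambda b: len(b.times))
        n = len(b.V)
        mid = np.asarray(b.V[int(0.2 * n):int(0.8 * n)])
        assert np.all(np.diff(mid) >= -1e-9)
        assert b.V[-1] > b.V[0]

    def test_simulated_v_tracks_stable_branch(self, p_cal, control_trace,
                                              control_metrics):
        """V follows the moving depolarized stable branch through the
        plateau (within the implementation's ~3 mV tracking lag)."""
        off = control_trace.stim_offset
        fb = track_branches(control_trace, p_cal, stride_ms=5.0,
                            t_start=off + 5.0,
                            t_stop=off + control_metrics.duration,
                            grid_mV=0.05)
        devs = []
        for i, t in enumerate(fb.eval_times):
            stable = [fp.V for fp in fb.roots[i] if fp.stability == "stable"]
            if stable:
                v = control_trace.V[control_trace.index_of(float(t))]
                devs.append(min(abs(v - sv) for sv in stable))
        assert np.mean(np.asarray(devs) < 3.0) >= 0.9

    def test_no_depolarized_branches_without_vgcc(self, p_cal):
        p = p_cal.replace(gbar_cal=0.0)
        roots = solve_fixed_points(0.05, p)
        assert all(r.V < p.E_pas + 15.0 for r in roots)

    def test_independent_cai_sweep_mode(self, p_cal):
        out = fixed_points_vs_cai([0.05, 0.1, 0.2], p_cal, grid_mV=0.05)
        assert set(out) == {0.05, 0.1, 0.2}
        assert all(isinstance(v, list) for v in out.values())


class TestIVTrajectory:
    def test_flat_resting_window(self, p_cal):
        from ca1plateau.protocols import StimulusProtocol
        from ca1plateau.simulate import simulate

        tr = simulate(p_cal, StimulusProtocol((), duration=300.0))
        iv = iv_trajectory(tr, (100.0, 101.0))
        assert np.max(np.abs(iv.I)) < 1e-9
        assert np.max(np.abs(iv.V - iv.V[0])) < 1e-6

    def test_sub_crosses_supra_does_not(self, proto_cal, threshold_50_tau10):
        th = threshold_50_tau10
        on = (proto_cal.step_onset or 0.0) + 50.0
        sub = iv_trajectory(th.sub_trace, (on, on + 60.0))
        supra = iv_trajectory(th.supra_trace, (on, on + 60.0))
        assert sub.crossed_to_inward
        assert not supra.crossed_to_inward

    def test_window_validation(self, control_trace):
        with pytest.raises(ValueError):
            iv_trajectory(control_trace, (100.0, 99.0))


class TestGateLagAndDynamicThreshold:
    def test_lag_zero_at_steady_state(self, p_cal):
        from ca1plateau.protocols import StimulusProtocol
        from ca1plateau.simulate import simulate

        tr = simulate(p_cal, StimulusProtocol((), duration=300.0))
        lag = gate_lag_analysis(tr, p_cal)
        assert abs(lag.lag_cal).max() < 1e-6
        assert abs(lag.lag_kca).max() < 1e-6

    def test_fast_ipsp_lags_more_than_slow(self, p_cal, proto_cal):
        from ca1plateau.plateau import find_termination_threshold
        from ca1plateau.simulate import simulate

        on = (proto_cal.step_onset or 0.0) + 50.0
        w = (on, on + 50.0)
        th_fast = find_termination_threshold(p_cal, proto_cal, 50.0, 5.0)
        th_slow = find_termination_threshold(p_cal, proto_cal, 50.0, 40.0)
        fast = gate_lag_analysis(
            simulate(p_cal, proto_cal.with_ipsg(50.0, th_fast.bracket[0], 5.0)),
            p_cal)
        slow = gate_lag_analysis(
            simulate(p_cal, proto_cal.with_ipsg(50.0, th_slow.bracket[0], 40.0)),
            p_cal)
        assert fast.max_lag_cal(w) > 3 * slow.max_lag_cal(w)

    def test_constructed_pair(self, p_passive):
        """A hand-built sub/supra pair returns exactly the sub trace's min V
        and the supra trace's initial fall speed."""
        sub = make_square_trace(p_passive, level=-10.0, t_off=700.0)
        m = (sub.t >= 300.0) & (sub.t < 330.0)
        sub.V[m] = -40.0  # dip to -40, recover
        supra = make_square_trace(p_passive, level=-10.0, t_off=700.0)
        k = supra.t >= 300.0
        supra.V[k] = np.maximum(-10.0 - 2.0 * (supra.t[k] - 300.0), -65.0)
        pts = estimate_dynamic_threshold([(sub, supra, 300.0)],
                                         dvdt_window=10.0)
        assert pts[0][1] == pytest.approx(-40.0)
        assert pts[0][0] == pytest.approx(2.0, rel=0.05)
        # duplicates pass through without averaging
        two = estimate_dynamic_threshold([(sub, supra, 300.0)] * 2)
        assert two[0] == two[1]

    def test_non_bracketing_pair_rejected(self, p_passive):
        flat = make_square_trace(p_passive, level=-10.0, t_off=700.0)
        with pytest.raises(ValueError, match="non-bracketing"):
            estimate_dynamic_threshold([(flat, flat, 300.0)])
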