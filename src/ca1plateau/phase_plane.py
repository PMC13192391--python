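"""Steady-state fixed-point analysis, I-V trajectories, gate-lag series, and
the dynamic termination threshold.

The quasi-steady reduction treats [Ca2+]i as frozen at its instantaneous
value and puts both gates at their steady states, which leaves the total
membrane current a function of V alone at each instant; its zeros are the
momentary fixed points.  A zero with dI/dV > 0 is stable (dV/dt = -I/Cm
pushes perturbations back) and one with dI/dV < 0 is repelling — the
termination threshold underlying all-or-none behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import bisect as _bisect

from . import mechanisms
from .params import ModelParameters
from .simulate import SimulationTrace

__all__ = [
    "FixedPoint",
    "Branch",
    "FixedPointBranches",
    "steady_state_current",
    "solve_fixed_points",
    "fixed_points_vs_cai",
    "track_branches",
    "iv_trajectory",
    "IVTrajectory",
    "gate_lag_analysis",
    "GateLag",
    "estimate_dynamic_threshold",
]


def steady_state_current(V, cai: float, p: ModelParameters,
                         g_syn: float = 0.0):
    """Total membrane current density (mA/cm2) with gates at steady state.

    m_cal = m_inf(V), m_kca = m_inf(cai), h = h(cai); cai is held fixed.
    Vectorized over V.
    """
    V = np.asarray(V, dtype=float)
    m = mechanisms.cal_rates(V, p).m_inf
    mk = mechanisms.kca_gate(cai, p).m_inf
    h = mechanisms.h_cal(cai, p)
    I = (p.g_pas * (V - p.E_pas)
         + p.gbar_cal * m * h * h * mechanisms.ghk_flux(V, cai, p.cao, p.temperature)
         + p.gbar_kca * mk ** 3 * (V - p.E_K)
         + g_syn * 1e-6 * (V - p.E_GABA) / p.area)
    return I if I.ndim else float(I)


@dataclass(frozen=True)
class FixedPoint:
    V: float
    stability: str   # "stable" | "repelling"
    cai: float


def solve_fixed_points(cai: float, p: ModelParameters, g_syn: float = 0.0, *,
                       v_range: tuple[float, float] = (-100.0, 20.0),
                       grid_mV: float = 0.01,
                       xtol: float = 1e-6) -> list[FixedPoint]:
    """All zeros of the quasi-steady current over ``v_range``, sorted by V.

    Dense-grid sign-change scan at ``grid_mV`` resolution followed by
    bisection refinement to ``xtol`` mV.  Stability from the sign of dI/dV.
    """
    v = np.arange(v_range[0], v_range[1] + 0.5 * grid_mV, grid_mV)
    I = steady_state_current(v, cai, p, g_syn)
    f = lambda x: steady_state_current(x, cai, p, g_syn)
    roots: list[float] = []
    exact = np.flatnonzero(I == 0.0)
    roots.extend(float(v[i]) for i in exact)
    sign_change = np.flatnonzero(np.sign(I[:-1]) * np.sign(I[1:]) < 0)
    for i in sign_change:
        roots.append(float(_bisect(f, v[i], v[i + 1], xtol=xtol)))
    roots.sort()
    out = []
    for r in roots:
        dIdV = (f(r + 1e-4) - f(r - 1e-4)) / 2e-4
        out.append(FixedPoint(V=r, stability="stable" if dIdV > 0 else "repelling",
                              cai=float(cai)))
    return out


def fixed_points_vs_cai(cai_grid: Sequence[float], p: ModelParameters,
                        g_syn: float = 0.0, **kw) -> dict[float, list[FixedPoint]]:
    """Fixed points over an independent cai sweep (not tied to a trace)."""
    return {float(c): solve_fixed_points(float(c), p, g_syn, **kw)
            for c in cai_grid}


@dataclass
class Branch:
    times: list[float] = field(default_factory=list)
    V: list[float] = field(default_factory=list)
    stability: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        """Majority stability along the branch."""
        n_stable = sum(s == "stable" for s in self.stability)
        return "stable" if 2 * n_stable >= len(self.stability) else "repelling"


@dataclass
class FixedPointBranches:
    eval_times: np.ndarray
    roots: list[list[FixedPoint]]    # per evaluation time, sorted by V
    branches: list[Branch]
    rest_V: float

    def plateau_range_branches(self, margin: float = 15.0) -> list[Branch]:
        """Branches lying above rest + margin (the plateau voltage range)."""
        out = []
        for b in self.branches:
            vs = np.asarray(b.V)
            if np.all(vs > self.rest_V + margin):
                out.append(b)
        return out

    def count_in_plateau_range(self, t: float, margin: float = 15.0) -> int:
        i = int(np.argmin(np.abs(self.eval_times - t)))
        return sum(fp.V > self.rest_V + margin for fp in self.roots[i])


def track_branches(trace: SimulationTrace, p: ModelParameters, *,
                   stride_ms: float = 2.0, t_start: float | None = None,
                   t_stop: float | None = None, grid_mV: float = 0.01,
                   jump_cap_mV: float = 5.0,
                   v_range: tuple[float, float] = (-100.0, 40.0)
                   ) -> FixedPointBranches:
    """Fixed points along a trace, linked into branches by V continuity.

    The quasi-steady current is solved at each subsampled time using the
    instantaneous cai(t); roots are linked to the nearest-V branch of the
    previous time point, with jumps above ``jump_cap_mV`` starting a new
    branch (a fold ends a branch rather than raising).
    """
    t0 = trace.t[0] if t_start is None else t_start
    t1 = trace.t[-1] if t_stop is None else t_stop
    times = np.arange(t0, t1 + 1e-9, stride_ms)
    roots_per_t: list[list[FixedPoint]] = []
    branches: list[Branch] = []
    active: dict[int, Branch] = {}
    for t in times:
        cai = float(trace.cai[trace.index_of(float(t))])
        roots = solve_fixed_points(cai, p, grid_mV=grid_mV, v_range=v_range)
        roots_per_t.append(roots)
        # greedy nearest-V matching between active branches and new roots
        unmatched = list(range(len(roots)))
        new_active: dict[int, Branch] = {}
        pairs = []
        for bid, br in active.items():
            for ri in unmatched:
                pairs.append((abs(roots[ri].V - br.V[-1]), bid, ri))
        taken_b: set[int] = set()
        taken_r: set[int] = set()
        for d, bid, ri in sorted(pairs):
            if d > jump_cap_mV or bid in taken_b or ri in taken_r:
                continue
            br = active[bid]
            br.times.append(float(t))
            br.V.append(roots[ri].V)
            br.stability.append(roots[ri].stability)
            new_active[ri] = br
            taken_b.add(bid)
            taken_r.add(ri)
        for ri in unmatched:
            if ri in taken_r:
                continue
            br = Branch([float(t)], [roots[ri].V], [roots[ri].stability])
            branches.append(br)
            new_active[ri] = br
        active = new_active
    # branches created mid-stream are already in `branches`; ensure the ones
    # present from the first step are too (they are — created on first step)
    return FixedPointBranches(times, roots_per_t, branches, trace.V_rest)


@dataclass
class IVTrajectory:
    t: np.ndarray
    V: np.ndarray
    I: np.ndarray
    crossings: list[tuple[float, float, str]]   # (t, V, "out_to_in"|"in_to_out")

    @property
    def crossed_to_inward(self) -> bool:
        return any(d == "out_to_in" for _, _, d in self.crossings)


def iv_trajectory(trace: SimulationTrace,
                  window: tuple[float, float]) -> IVTrajectory:
    """The (V, I_sum) path over a time window, with I = 0 crossing report.

    Since dV/dt = -I_sum/Cm, a crossing of I = 0 is exactly a slope reversal
    of V; a crossing from net outward to net inward ("out_to_in") is the
    subthreshold rebound past the repelling point back toward the plateau.
    """
    t0, t1 = window
    if t0 < trace.t[0] or t1 > trace.t[-1] + 1e-9 or t1 <= t0:
        raise ValueError("window outside trace")
    i0, i1 = trace.index_of(t0), trace.index_of(t1) + 1
    t = trace.t[i0:i1]
    V = trace.V[i0:i1]
    I = trace.I_sum[i0:i1]
    crossings = []
    s = np.sign(I)
    for k in np.flatnonzero(s[:-1] * s[1:] < 0):
        frac = I[k] / (I[k] - I[k + 1])
        tc = t[k] + frac * (t[k + 1] - t[k])
        vc = V[k] + frac * (V[k + 1] - V[k])
        direction = "out_to_in" if I[k] > 0 else "in_to_out"
        crossings.append((float(tc), float(vc), direction))
    return IVTrajectory(t=t, V=V, I=I, crossings=crossings)


@dataclass
class GateLag:
    t: np.ndarray
    lag_cal: np.ndarray    # m_cal - m_inf_cal(V(t))
    lag_kca: np.ndarray    # m_kca - m_inf_kca(cai(t))

    def max_lag_cal(self, window: tuple[float, float] | None = None) -> float:
        return self._max(self.lag_cal, window)

    def max_lag_kca(self, window: tuple[float, float] | None = None) -> float:
        return self._max(self.lag_kca, window)

    def _max(self, lag: np.ndarray, window) -> float:
        if window is None:
            return float(np.max(np.abs(lag)))
        m = (self.t >= window[0]) & (self.t <= window[1])
        return float(np.max(np.abs(lag[m])))


def gate_lag_analysis(trace: SimulationTrace, p: ModelParameters) -> GateLag:
    """Per-sample gate lag: how far each gate sits from its moving target.

    During a fast IPSP the VGCC m-gate cannot follow the rapid
    hyperpolarization, so m stays high while m_inf collapses — the lag that
    lets I_VGCC grow with the Ca2+ driving force and resist termination.
    """
    return GateLag(
        t=trace.t,
        lag_cal=trace.m_cal - trace.m_inf_cal,
        lag_kca=trace.m_kca - trace.m_inf_kca,
    )


def estimate_dynamic_threshold(
    pairs: Iterable[tuple[SimulationTrace, SimulationTrace, float]], *,
    minv_window: float = 100.0, dvdt_window: float = 10.0,
    rest_tol: float = 5.0,
) -> list[tuple[float, float]]:
    """Dynamic termination threshold vs approach speed, one point per pair.

    For each (just-subthreshold trace, just-suprathreshold trace, onset):
    the threshold estimate is the most hyperpolarized V reached by the
    subthreshold IPSP, and the approach speed is the maximal hyperpolarizing
    dV/dt of the suprathreshold IPSP (measured over its initial
    ``dvdt_window`` ms, the synaptically driven phase).
    """
    from .plateau import measure_ipsp_features

    out = []
    for sub, supra, onset in pairs:
        f_sub = measure_ipsp_features(sub, onset, minv_window)
        f_sup = measure_ipsp_features(supra, onset, minv_window)
        # bracket sanity: supra must reach the resting band, sub must not
        if f_sup.min_V > supra.V_rest + rest_tol:
            raise ValueError("supra trace does not terminate (non-bracketing pair)")
        if f_sub.min_V <= sub.V_rest + rest_tol:
            raise ValueError("sub trace reaches rest (non-bracketing pair)")
        speed = measure_ipsp_features(supra, onset, dvdt_window).max_dVdt
        out.append((speed, f_sub.min_V))
    return out
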