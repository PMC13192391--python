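"""Plateau detection, termination classification, all-or-none threshold search,
and the timing and amplitude x decay-tau sweeps.

Operational definitions
-----------------------
A *plateau* is present when, after the depolarizing step ends, V stays above
the half-repolarization level — the midpoint between V measured 5 ms after
stimulus offset and the resting V — for at least 20 ms.  *Duration* runs from
stimulus offset to the end of the last 20 ms-sustained epoch above that
level: a transient IPSP dip below the level from which the plateau recovers
does not end the plateau, while a terminal repolarization (V never again
sustained above the level) does.  A trial counts as *terminated* by an
inhibitory event only if V reaches within 5 mV of rest within 100 ms of the
event onset AND the plateau time remaining after the event is under half of
the control's remaining time: an IPSP transient that the plateau survives is
not a termination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters
from .protocols import MockIPSP, StimulusProtocol
from .simulate import SimulationTrace, simulate

__all__ = [
    "DetectionConfig",
    "PlateauMetrics",
    "TerminationVerdict",
    "ThresholdResult",
    "SweepResult",
    "UnterminableError",
    "detect_plateau",
    "classify_termination",
    "find_termination_threshold",
    "find_mock_ipsp_threshold",
    "sweep_timing",
    "sweep_amp_tau",
    "threshold_vs_tau",
    "measure_ipsp_features",
    "bisect_threshold",
]


class UnterminableError(RuntimeError):
    """No terminating amplitude found within the doubling budget."""


@dataclass(frozen=True)
class DetectionConfig:
    ref_delay_ms: float = 5.0     # V reference sampled this long after offset
    persist_ms: float = 20.0      # crossing must persist this long
    rest_tol_mV: float = 5.0      # "reached rest" band for termination
    term_window_ms: float = 100.0 # deadline after event onset to reach rest
    min_depol_mV: float = 20.0    # V_ref must exceed rest by this to count
    crossing_smooth_ms: float = 1.0  # V smoothing before threshold tests
    duration_ratio: float = 0.5   # trial/control duration bound for termination
    break_smooth_ms: float = 0.5  # V smoothing for the break-point estimate


@dataclass(frozen=True)
class PlateauMetrics:
    plateau_present: bool
    onset: float                  # ms, plateau initiation (= step onset)
    duration: float               # ms from stimulus offset; inf if nonrepolarizing
    plateau_level: float          # mV, median V while above the half level
    break_point_V: float          # mV at maximal repolarization speed; nan if n/a
    break_time: float             # ms (absolute trace time); nan if n/a
    nonrepolarizing: bool
    half_level: float             # mV, the crossing level used
    rest_V: float                 # mV


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of consecutive-True runs (stop exclusive)."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], splits + 1))
    ends = np.concatenate((splits, [len(idx) - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def _last_sustained_end(above: np.ndarray, n_persist: int) -> int | None:
    """End index (exclusive) of the last run of >= n_persist True values."""
    runs = [r for r in _runs(above) if r[1] - r[0] >= n_persist]
    return runs[-1][1] if runs else None


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    """Boxcar smoothing with edge-replicated padding (no edge artifacts)."""
    if n <= 1 or x.size < 2:
        return x
    pad = np.concatenate((np.full(n, x[0]), x, np.full(n, x[-1])))
    kernel = np.ones(n) / n
    return np.convolve(pad, kernel, mode="same")[n:-n]


def detect_plateau(trace: SimulationTrace,
                   cfg: DetectionConfig = DetectionConfig()) -> PlateauMetrics:
    """Detect a plateau and measure its duration relative to stimulus offset."""
    offset = trace.stim_offset
    if offset is None:
        raise ValueError("trace protocol has no current step (no stimulus offset)")
    if offset + cfg.ref_delay_ms >= trace.t[-1]:
        raise ValueError("trace shorter than the stimulus")
    dt = trace.dt
    onset = trace.protocol.step_onset
    i_off = trace.index_of(offset)
    # smoothed V for all level comparisons: averages recording noise away
    # without moving the (much slower) repolarization crossing
    V = _smooth(trace.V, max(int(round(cfg.crossing_smooth_ms / dt)), 1))
    rest = float(V[0])
    v_ref = float(V[trace.index_of(offset + cfg.ref_delay_ms)])
    half = 0.5 * (v_ref + rest)
    n_persist = max(int(round(cfg.persist_ms / dt)), 1)

    depolarized = v_ref >= rest + cfg.min_depol_mV
    above = V[i_off:] >= half
    end = _last_sustained_end(above, n_persist)
    if end is None:
        duration = 0.0
        nonrepolarizing = False
    elif end >= len(above):
        duration = math.inf
        nonrepolarizing = True
    else:
        duration = end * dt
        nonrepolarizing = False
    present = depolarized and duration >= cfg.persist_ms

    if present:
        i_end = len(trace) if nonrepolarizing else i_off + end
        seg = trace.V[i_off:i_end]
        level = float(np.median(seg[seg >= half])) if np.any(seg >= half) else v_ref
    else:
        level = v_ref

    break_V = math.nan
    break_time = math.nan
    if present and not nonrepolarizing:
        # break point = maximal repolarization speed during the final
        # approach to rest (the 40 ms preceding the first return to the
        # resting band after the plateau ends); nan if V never gets there
        idx_end = i_off + end
        at_rest = np.flatnonzero(trace.V[idx_end:] <= rest + cfg.rest_tol_mV)
        if at_rest.size:
            hi = idx_end + int(at_rest[0]) + 1
            lo = max(i_off, hi - int(round(40.0 / dt)))
            vs = _smooth(trace.V[lo:hi],
                         max(int(round(cfg.break_smooth_ms / dt)), 1))
            dv = np.gradient(vs, dt)
            k = int(np.argmin(dv))
            break_V = float(vs[k])
            break_time = float(trace.t[lo + k])

    return PlateauMetrics(
        plateau_present=bool(present),
        onset=float(onset) if onset is not None else math.nan,
        duration=float(duration),
        plateau_level=level,
        break_point_V=break_V,
        break_time=break_time,
        nonrepolarizing=bool(nonrepolarizing),
        half_level=float(half),
        rest_V=float(rest),
    )


@dataclass(frozen=True)
class TerminationVerdict:
    terminated: bool
    termination_time: float       # ms (absolute), nan if not terminated
    trial_duration: float         # ms from stimulus offset


def classify_termination(trial: SimulationTrace, control: PlateauMetrics,
                         ipsg_onset: float,
                         cfg: DetectionConfig = DetectionConfig()) -> TerminationVerdict:
    """Decide whether an inhibitory event at ``ipsg_onset`` (absolute protocol
    time, ms) terminated the plateau, relative to the no-event control."""
    if not control.plateau_present:
        raise ValueError("control trace has no plateau")
    offset = trial.stim_offset
    plateau_end = offset + control.duration
    if not (control.onset <= ipsg_onset <= plateau_end):
        raise ValueError(
            f"event onset {ipsg_onset} ms lies outside the control plateau "
            f"[{control.onset}, {plateau_end}] ms"
        )
    tm = detect_plateau(trial, cfg)
    # (a) V reaches the resting band soon after the event
    i0 = trial.index_of(ipsg_onset)
    i1 = min(len(trial), trial.index_of(ipsg_onset + cfg.term_window_ms) + 1)
    near_rest = np.flatnonzero(
        trial.V[i0:i1] <= trial.V_rest + cfg.rest_tol_mV
    )
    reached = near_rest.size > 0
    # (b) the plateau time remaining after the event is cut to under half of
    # the control's remaining time (an IPSP transient does not qualify)
    remaining_trial = max(offset + tm.duration - ipsg_onset, 0.0)
    remaining_control = max(plateau_end - ipsg_onset, 0.0)
    shorter = remaining_trial < cfg.duration_ratio * remaining_control
    terminated = bool(reached and shorter)
    t_term = float(trial.t[i0 + near_rest[0]]) if terminated else math.nan
    return TerminationVerdict(terminated, t_term, tm.duration)


def bisect_threshold(verdict: Callable[[float], bool], *, seed: float = 1e-5,
                     rel_tol: float = 0.005, max_doublings: int = 30,
                     max_iter: int = 60) -> tuple[float, float]:
    """Smallest terminating amplitude by doubling + bisection.

    ``verdict(g)`` must be True for sufficiently large g.  Returns the final
    bracket ``(sub, supra)`` with (supra - sub)/supra <= rel_tol.
    """
    if seed <= 0:
        raise ValueError("seed must be positive")
    hi = seed
    lo = 0.0
    n = 0
    while not verdict(hi):
        lo = hi
        hi *= 2.0
        n += 1
        if n > max_doublings:
            raise UnterminableError(
                f"no terminating amplitude up to {hi:g} "
                f"({max_doublings} doublings from seed {seed:g})"
            )
    for _ in range(max_iter):
        if lo > 0 and (hi - lo) / hi <= rel_tol:
            break
        mid = 0.5 * (lo + hi) if lo > 0 else hi / 2.0
        if verdict(mid):
            hi = mid
        else:
            lo = mid
    return lo, hi


@dataclass
class ThresholdResult:
    g_star: float                 # uS (or mA/cm2 for mock-IPSP searches)
    bracket: tuple[float, float]
    rel_tol: float
    sub_trace: SimulationTrace | None
    supra_trace: SimulationTrace | None
    sub_verdict: TerminationVerdict | None
    supra_verdict: TerminationVerdict | None
    onset: float                  # ms from plateau initiation
    tau: float                    # ms (tau_syn or tau_decay)
    control: PlateauMetrics | None


def _threshold_search(p: ModelParameters, proto: StimulusProtocol,
                      make_trial: Callable[[float], StimulusProtocol],
                      onset_abs: float, onset_rel: float, tau: float,
                      cfg: DetectionConfig, seed: float, rel_tol: float,
                      verdict_fn: Callable[[float], bool] | None) -> ThresholdResult:
    if verdict_fn is not None:
        lo, hi = bisect_threshold(verdict_fn, seed=seed, rel_tol=rel_tol)
        return ThresholdResult(hi, (lo, hi), rel_tol, None, None, None, None,
                               onset_rel, tau, None)
    control = detect_plateau(simulate(p, proto), cfg)
    if not control.plateau_present:
        raise ValueError("protocol does not evoke a plateau without inhibition")

    def verdict(g: float) -> bool:
        trial = simulate(p, make_trial(g))
        return classify_termination(trial, control, onset_abs, cfg).terminated

    lo, hi = bisect_threshold(verdict, seed=seed, rel_tol=rel_tol)
    sub = simulate(p, make_trial(lo)) if lo > 0 else simulate(p, proto)
    supra = simulate(p, make_trial(hi))
    return ThresholdResult(
        g_star=hi, bracket=(lo, hi), rel_tol=rel_tol,
        sub_trace=sub, supra_trace=supra,
        sub_verdict=classify_termination(sub, control, onset_abs, cfg),
        supra_verdict=classify_termination(supra, control, onset_abs, cfg),
        onset=onset_rel, tau=tau, control=control,
    )


def find_termination_threshold(p: ModelParameters, plateau_proto: StimulusProtocol,
                               ipsg_onset: float, tau_syn: float, *,
                               cfg: DetectionConfig = DetectionConfig(),
                               seed: float = 1e-5, rel_tol: float = 0.005,
                               verdict_fn: Callable[[float], bool] | None = None
                               ) -> ThresholdResult:
    """All-or-none IPSG threshold at a given onset (ms from plateau initiation).

    Bisects the IPSG peak conductance (uS) until the non-terminating /
    terminating bracket is tighter than ``rel_tol`` (relative).  A
    ``verdict_fn`` may be injected in place of the simulation pipeline.
    """
    onset_abs = (plateau_proto.step_onset or 0.0) + ipsg_onset
    return _threshold_search(
        p, plateau_proto,
        lambda g: plateau_proto.with_ipsg(ipsg_onset, g, tau_syn),
        onset_abs, ipsg_onset, tau_syn, cfg, seed, rel_tol, verdict_fn,
    )


def find_mock_ipsp_threshold(p: ModelParameters, plateau_proto: StimulusProtocol,
                             onset: float, tau_decay: float = 30.0, *,
                             cfg: DetectionConfig = DetectionConfig(),
                             seed: float = 1e-5, rel_tol: float = 0.005
                             ) -> ThresholdResult:
    """Threshold amplitude (mA/cm2) of an IPSP-mimicking injected current."""
    onset_abs = (plateau_proto.step_onset or 0.0) + onset

    def make(amp: float) -> StimulusProtocol:
        return plateau_proto.with_events(MockIPSP(onset_abs, amp, tau_decay))

    return _threshold_search(p, plateau_proto, make, onset_abs, onset,
                             tau_decay, cfg, seed, rel_tol, None)


@dataclass
class SweepResult:
    """Tidy per-cell verdicts for a parameter sweep."""

    axes: dict[str, np.ndarray]
    table: pd.DataFrame           # one row per grid cell

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep_timing(p: ModelParameters, plateau_proto: StimulusProtocol,
                 g_max: float, tau_syn: float, times: Sequence[float], *,
                 cfg: DetectionConfig = DetectionConfig()) -> SweepResult:
    """Termination verdicts for one IPSG amplitude delivered at several times
    (ms from plateau initiation)."""
    times = np.asarray(sorted(times), dtype=float)
    control = detect_plateau(simulate(p, plateau_proto), cfg)
    if not control.plateau_present:
        raise ValueError("protocol does not evoke a plateau")
    step_on = plateau_proto.step_onset or 0.0
    plateau_end_rel = control.duration + (plateau_proto.stim_offset - step_on)
    rows = []
    for t in times:
        if g_max > 0 and t > plateau_end_rel:
            rows.append(dict(time=t, applicable=False, terminated=False,
                             termination_time=math.nan, duration=math.nan))
            continue
        trial = simulate(p, plateau_proto.with_ipsg(t, g_max, tau_syn))
        if g_max == 0:
            tm = detect_plateau(trial, cfg)
            rows.append(dict(time=t, applicable=True, terminated=False,
                             termination_time=math.nan, duration=tm.duration))
            continue
        v = classify_termination(trial, control, step_on + t, cfg)
        rows.append(dict(time=t, applicable=True, terminated=v.terminated,
                         termination_time=v.termination_time,
                         duration=v.trial_duration))
    return SweepResult(axes={"time": times}, table=pd.DataFrame(rows))


def sweep_amp_tau(p: ModelParameters, plateau_proto: StimulusProtocol,
                  amp_grid: Sequence[float], tau_grid: Sequence[float],
                  onset: float, *,
                  cfg: DetectionConfig = DetectionConfig()) -> SweepResult:
    """Verdict matrix over IPSG amplitude (uS) x decay tau (ms) at one onset."""
    amps = np.asarray(amp_grid, dtype=float)
    taus = np.asarray(tau_grid, dtype=float)
    if np.any(np.diff(amps) <= 0) or np.any(np.diff(taus) <= 0):
        raise ValueError("grids must be strictly increasing")
    control = detect_plateau(simulate(p, plateau_proto), cfg)
    step_on = plateau_proto.step_onset or 0.0
    rows = []
    for a in amps:
        for tau in taus:
            if a == 0:
                rows.append(dict(amplitude=a, tau=tau, terminated=False,
                                 termination_time=math.nan,
                                 duration=control.duration))
                continue
            trial = simulate(p, plateau_proto.with_ipsg(onset, a, tau))
            v = classify_termination(trial, control, step_on + onset, cfg)
            rows.append(dict(amplitude=a, tau=tau, terminated=v.terminated,
                             termination_time=v.termination_time,
                             duration=v.trial_duration))
    return SweepResult(axes={"amplitude": amps, "tau": taus},
                       table=pd.DataFrame(rows))


def threshold_vs_tau(p: ModelParameters, plateau_proto: StimulusProtocol,
                     taus: Sequence[float], onset: float, *,
                     cfg: DetectionConfig = DetectionConfig(),
                     rel_tol: float = 0.005) -> list[ThresholdResult]:
    """Just-terminating IPSG amplitude for each decay tau at a fixed onset."""
    return [
        find_termination_threshold(p, plateau_proto, onset, tau,
                                   cfg=cfg, rel_tol=rel_tol)
        for tau in taus
    ]


@dataclass(frozen=True)
class IpspFeatures:
    min_V: float           # mV
    ipsp_amplitude: float  # mV, pre-onset V minus min V
    max_dVdt: float        # mV/ms, maximal hyperpolarizing rate (positive number)


def measure_ipsp_features(trace: SimulationTrace, onset: float,
                          window: float) -> IpspFeatures:
    """Depth and maximal hyperpolarizing speed of an IPSP transient."""
    if onset < trace.t[0] or onset > trace.t[-1]:
        raise ValueError("onset outside trace")
    i0 = trace.index_of(onset)
    i1 = trace.index_of(onset + window) + 1
    if i1 > len(trace):
        import warnings

        warnings.warn("IPSP window truncated to trace end", stacklevel=2)
        i1 = len(trace)
    seg = trace.V[i0:i1]
    v_pre = float(trace.V[max(i0 - 1, 0)])
    min_V = float(seg.min())
    dv = np.gradient(seg, trace.dt) if seg.size > 1 else np.zeros(1)
    max_fall = float(max(-dv.min(), 0.0))
    return IpspFeatures(min_V=min_V, ipsp_amplitude=v_pre - min_V,
                        max_dVdt=max_fall)
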