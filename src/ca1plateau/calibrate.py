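"""Grid-search calibration of the unprinted VGCC and SK conductance scales.

The two maximal conductance/permeability scales are not constrained by the
printed equations, so they are chosen empirically: every grid cell is driven
with the standard ignition protocol — a brief (10 ms) step at twice the
cell's minimal plateau-evoking amplitude, so the plateau is fully established
before the earliest inhibition times probed later — and scored by its plateau
duration.  The feasible set is the region producing repolarizing plateaus
inside a target band bracketing the experimental mean duration (140 ms), and
the selected cell is the feasible one closest to the band midpoint.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters
from .plateau import DetectionConfig, PlateauMetrics, detect_plateau
from .protocols import StimulusProtocol, step_protocol
from .simulate import NoRestingStateError, SimulationError, simulate

__all__ = [
    "CalibrationResult",
    "NoPlateauError",
    "default_axes",
    "find_step_amplitude",
    "grid_search",
    "pharmacology_scan",
    "standard_protocol",
]


class NoPlateauError(RuntimeError):
    """No step amplitude evokes a plateau for this parameter set."""


def default_axes(n: int = 20) -> dict[str, np.ndarray]:
    """Log-spaced default calibration axes.

    The box is centred on the region where the GHK-flux VGCC (with its strong
    Ca2+-dependent h^2 inactivation at ki = 1e-3 mM) can balance leak + SK at
    plateau voltages: gbar_cal in [5e-2, 1], gbar_kca in [2e-6, 2e-4].
    """
    return {
        "gbar_cal": np.geomspace(5e-2, 1.0, n),
        "gbar_kca": np.geomspace(2e-6, 2e-4, n),
    }


DEFAULT_STEP_MS = 10.0
DEFAULT_STEP_ONSET = 10.0
DEFAULT_AMP_MULT = 2.0


def _template(proto: StimulusProtocol | None) -> StimulusProtocol:
    return proto or step_protocol(0.0, onset=DEFAULT_STEP_ONSET,
                                  step_ms=DEFAULT_STEP_MS, duration=900.0)


def _with_amplitude(proto: StimulusProtocol, amp: float) -> StimulusProtocol:
    return step_protocol(
        amp, onset=proto.step_onset if proto.step_onset is not None else DEFAULT_STEP_ONSET,
        step_ms=(proto.stim_offset - proto.step_onset) if proto.stim_offset is not None
        else DEFAULT_STEP_MS,
        duration=proto.duration, settle=proto.settle,
    )


def find_step_amplitude(p: ModelParameters, *, proto: StimulusProtocol | None = None,
                        seed: float = 2.5e-4, rel_tol: float = 0.02,
                        max_doublings: int = 20,
                        cfg: DetectionConfig = DetectionConfig()) -> float:
    """Smallest (just-suprathreshold) step current density evoking a plateau.

    Doubles (or halves) the amplitude from ``seed`` (mA/cm2) until the
    plateau/no-plateau boundary is bracketed, then bisects to ``rel_tol``;
    returns the suprathreshold edge.
    """
    proto = _template(proto)

    def has_plateau(amp: float) -> bool:
        try:
            return detect_plateau(
                simulate(p, _with_amplitude(proto, amp)), cfg
            ).plateau_present
        except SimulationError:
            return False

    if has_plateau(seed):
        # seed is suprathreshold: halve down to bracket the threshold
        hi = seed
        lo = seed / 2.0
        for _ in range(max_doublings):
            if not has_plateau(lo):
                break
            hi = lo
            lo /= 2.0
        else:
            lo = 0.0  # plateau at arbitrarily small amplitude (spontaneous-ish)
    else:
        hi = 2.0 * seed
        lo = seed
        for _ in range(max_doublings):
            if has_plateau(hi):
                break
            lo = hi
            hi *= 2.0
        else:
            raise NoPlateauError(
                f"no plateau up to {hi:g} mA/cm2 ({max_doublings} doublings)"
            )
    while lo > 0 and (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if has_plateau(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class CalibrationResult:
    axes: dict[str, np.ndarray]
    table: pd.DataFrame              # one row per grid cell
    target_band: tuple[float, float]
    selected: ModelParameters | None
    selected_duration: float

    @property
    def feasible(self) -> pd.DataFrame:
        return self.table[self.table.feasible]


def grid_search(base: ModelParameters,
                axes: Mapping[str, Sequence[float]] | None = None,
                target_band: tuple[float, float] = (100.0, 200.0),
                proto: StimulusProtocol | None = None, *,
                amp_mult: float = DEFAULT_AMP_MULT,
                cfg: DetectionConfig = DetectionConfig(),
                select_robust: bool = True, max_screened: int = 10,
                progress: bool = False) -> CalibrationResult:
    """Score every cell of a conductance grid by its plateau duration.

    Each cell is simulated with the standard ignition protocol: a brief step
    at ``amp_mult`` times its own minimal plateau-evoking amplitude.  Cells
    are labeled ``no_rest`` (spontaneously active), ``no_plateau``,
    ``nonrepolarizing``, or ``ok``; feasible cells are the ``ok`` ones whose
    duration falls inside ``target_band``.

    Selection walks the feasible cells from the band midpoint outward and,
    when ``select_robust`` is set, returns the first one that also passes
    the robustness screen (stable rest without SK; all-or-none termination);
    with the screen off (or if nothing passes among the ``max_screened``
    closest) it is simply the cell nearest the midpoint.
    """
    axes = {k: np.asarray(v, dtype=float) for k, v in (axes or default_axes()).items()}
    proto = _template(proto)
    names = list(axes)
    mid = 0.5 * (target_band[0] + target_band[1])
    rows = []
    cells = list(itertools.product(*(axes[k] for k in names)))
    iterator = cells
    if progress:
        from tqdm import tqdm  # type: ignore[import-untyped]

        iterator = tqdm(cells, desc="grid search")
    for values in iterator:
        cell = dict(zip(names, values))
        row = dict(cell)
        p = base.replace(**cell)
        try:
            amp = amp_mult * find_step_amplitude(p, proto=proto, cfg=cfg)
            m = detect_plateau(simulate(p, _with_amplitude(proto, amp)), cfg)
            if m.nonrepolarizing:
                status = "nonrepolarizing"
            elif not m.plateau_present:
                status = "no_plateau"
            else:
                status = "ok"
            row.update(status=status, amplitude=amp, duration=m.duration,
                       plateau_level=m.plateau_level)
        except NoRestingStateError:
            row.update(status="no_rest", amplitude=math.nan,
                       duration=math.nan, plateau_level=math.nan)
        except (NoPlateauError, SimulationError):
            row.update(status="no_plateau", amplitude=math.nan,
                       duration=math.nan, plateau_level=math.nan)
        row["feasible"] = (
            row["status"] == "ok"
            and target_band[0] <= row["duration"] <= target_band[1]
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    feas = table[table.feasible]
    if feas.empty:
        return CalibrationResult(axes, table, target_band, None, math.nan)
    order = feas.assign(dist=(feas.duration - mid).abs()).sort_values("dist")
    if select_robust:
        for _, cand in order.head(max_screened).iterrows():
            p = base.replace(**{k: float(cand[k]) for k in names})
            if _robust_cell(p, proto, cfg):
                return CalibrationResult(axes, table, target_band, p,
                                         float(cand.duration))
    best = order.iloc[0]
    selected = base.replace(**{k: float(best[k]) for k in names})
    return CalibrationResult(axes, table, target_band, selected,
                             float(best.duration))


def _robust_cell(p: ModelParameters, proto: StimulusProtocol,
                 cfg: DetectionConfig) -> bool:
    """Screen a feasible cell for the two robustness properties the analyses
    rely on: (1) the resting state survives removal of the SK conductance
    (its experimental counterpart, SK block, leaves the resting cell at
    rest); (2) the inhibitory termination at mid-plateau is all-or-none (a
    > 50 ms duration jump across the bisected threshold bracket)."""
    from .plateau import find_termination_threshold
    from .simulate import initialize_rest

    try:
        r0 = initialize_rest(p)
        r1 = initialize_rest(p.replace(gbar_kca=0.0))
        if abs(r1.V - r0.V) > 15.0:
            return False
        th = find_termination_threshold(
            p, standard_protocol(p, proto=proto, cfg=cfg), 50.0, 10.0, cfg=cfg
        )
        jump = (th.sub_verdict.trial_duration - th.supra_verdict.trial_duration)
        return jump > 50.0
    except Exception:
        return False


def standard_protocol(p: ModelParameters, *,
                      proto: StimulusProtocol | None = None,
                      amp_mult: float = DEFAULT_AMP_MULT,
                      cfg: DetectionConfig = DetectionConfig()) -> StimulusProtocol:
    """The standard plateau-evoking protocol for a parameter set: a brief
    ignition step at ``amp_mult`` times the minimal plateau-evoking
    amplitude."""
    proto = _template(proto)
    amp = amp_mult * find_step_amplitude(p, proto=proto, cfg=cfg)
    return _with_amplitude(proto, amp)


def pharmacology_scan(p_calibrated: ModelParameters,
                      proto: StimulusProtocol | None = None, *,
                      amp_mult: float = DEFAULT_AMP_MULT,
                      cfg: DetectionConfig = DetectionConfig()
                      ) -> dict[str, PlateauMetrics | None]:
    """Model analogs of the channel-block experiments.

    Conditions: ``baseline``; ``cd`` (gbar_cal = 0, the Cd2+ analog) at the
    baseline step amplitude and at 3x (``cd_3x``); ``apamin`` (gbar_kca = 0).
    Values are plateau metrics, or None when the simulation itself fails.
    """
    proto = _template(proto)
    amp = amp_mult * find_step_amplitude(p_calibrated, proto=proto, cfg=cfg)

    def run(p: ModelParameters, amplitude: float) -> PlateauMetrics | None:
        try:
            return detect_plateau(simulate(p, _with_amplitude(proto, amplitude)), cfg)
        except (SimulationError, NoRestingStateError):
            return None

    return {
        "baseline": run(p_calibrated, amp),
        "cd": run(p_calibrated.replace(gbar_cal=0.0), amp),
        "cd_3x": run(p_calibrated.replace(gbar_cal=0.0), 3.0 * amp),
        "apamin": run(p_calibrated.replace(gbar_kca=0.0), amp),
    }
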