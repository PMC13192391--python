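"""Steady-state fixed points during the plateau.

Solves the quasi-steady membrane current for I = 0 along the control
plateau: a depolarized stable branch tracked by V, and a repelling
(threshold) branch that drifts toward depolarized values — the reason
early inhibition fails.  Also dissects the current balance.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ca1plateau.calibrate import standard_protocol
from ca1plateau.params import calibrated_parameters
from ca1plateau.phase_plane import track_branches
from ca1plateau.plateau import detect_plateau
from ca1plateau.simulate import simulate

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

p = calibrated_parameters()
proto = standard_protocol(p)
tr = simulate(p, proto)
m = detect_plateau(tr)
fb = track_branches(tr, p, stride_ms=5.0, t_start=proto.stim_offset,
                    t_stop=m.break_time, grid_mV=0.05)
rows = []
for bid, b in enumerate(fb.branches):
    for t, v, s in zip(b.times, b.V, b.stability):
        rows.append(dict(branch=bid, t=t, V=v, stability=s, label=b.label))
pd.DataFrame(rows).to_csv(OUT / "fixed_point_branches.csv", index=False)
counts = {t: fb.count_in_plateau_range(t)
          for t in (40.0, 70.0, 100.0, 130.0, 160.0)}
print("fixed points in the plateau range (V > rest + 15 mV):", counts)
# current balance mid-plateau
off = proto.stim_offset
j0, j1 = tr.index_of(off + 0.2 * m.duration), tr.index_of(off + 0.8 * m.duration)
dom = np.maximum(np.abs(tr.I_VGCC[j0:j1]), np.abs(tr.I_KCa[j0:j1]))
ratio = np.abs(tr.I_sum[j0:j1]) / dom
bal = {"max_net_over_dominant": float(ratio.max()),
       "mean_net_over_dominant": float(ratio.mean())}
(OUT / "current_balance.json").write_text(json.dumps(bal, indent=2))
print(f"net current is {100*bal['mean_net_over_dominant']:.1f}% of the "
      f"dominant current on average mid-plateau (max "
      f"{100*bal['max_net_over_dominant']:.1f}%)")
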