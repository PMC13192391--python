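"""Early resistance: termination vs IPSG delivery time.

The just-threshold-at-50 ms IPSG is delivered at 10..100 ms from plateau
initiation, at 1x / 2x / 4x amplitude.  Early deliveries fail; larger
amplitudes terminate earlier.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from ca1plateau.calibrate import standard_protocol
from ca1plateau.params import calibrated_parameters
from ca1plateau.plateau import find_termination_threshold, sweep_timing

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

p = calibrated_parameters()
proto = standard_protocol(p)
th = find_termination_threshold(p, proto, 50.0, 10.0)
times = np.arange(10.0, 100.1, 5.0)
frames = []
for mult in (1.0, 2.0, 4.0):
    sw = sweep_timing(p, proto, mult * th.g_star, 10.0, times)
    sw.table["amplitude_mult"] = mult
    frames.append(sw.table)
    verd = "".join("T" if t else "." for t in sw.table.terminated)
    first = sw.table[sw.table.terminated].time.min()
    print(f"{mult:>3}x g*: earliest terminating onset "
          f"{first if np.isfinite(first) else 'none'} ms   [{verd}]")
out = pd.concat(frames, ignore_index=True)
out.to_csv(OUT / "timing_sweep.csv", index=False)
print(f"-> {OUT/'timing_sweep.csv'}")
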