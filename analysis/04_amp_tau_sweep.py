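"""IPSG amplitude x decay-tau parameter space.

For each decay tau in {5,10,20,40,80} ms, bisects the minimal terminating
amplitude at 50 ms; slower IPSGs terminate at smaller amplitudes.  Also
writes the full verdict matrix on an amplitude grid around threshold.
"""
import json
from pathlib import Path

import numpy as np

from ca1plateau.calibrate import standard_protocol
from ca1plateau.params import calibrated_parameters
from ca1plateau.plateau import sweep_amp_tau, threshold_vs_tau

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

p = calibrated_parameters()
proto = standard_protocol(p)
taus = [5.0, 10.0, 20.0, 40.0, 80.0]
ths = threshold_vs_tau(p, proto, taus, onset=50.0)
table = {str(tau): th.g_star for tau, th in zip(taus, ths)}
(OUT / "threshold_vs_tau.json").write_text(json.dumps(table, indent=2))
for tau, th in zip(taus, ths):
    print(f"tau = {tau:5.1f} ms -> minimal terminating IPSG {th.g_star:.4g} uS")
amps = ths[1].g_star * np.geomspace(0.25, 4.0, 9)
sw = sweep_amp_tau(p, proto, amps, taus, onset=50.0)
sw.to_csv(OUT / "amp_tau_sweep.csv")
print(f"-> {OUT/'amp_tau_sweep.csv'}")
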