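"""Channel-block analogs: VGCC block (Cd2+-like) and SK block (apamin-like).

VGCC removal abolishes the plateau even at threefold drive; SK removal
lengthens it; IPSP-mimicking current injections still terminate plateaus
without SK (termination needs hyperpolarization, not the SK current).
"""
import json
from pathlib import Path

from ca1plateau.calibrate import pharmacology_scan, standard_protocol
from ca1plateau.params import calibrated_parameters
from ca1plateau.plateau import find_mock_ipsp_threshold

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

p = calibrated_parameters()
scan = pharmacology_scan(p)
out = {k: (None if m is None else
           {"plateau_present": m.plateau_present, "duration_ms": m.duration,
            "nonrepolarizing": m.nonrepolarizing})
       for k, m in scan.items()}
for k, v in out.items():
    print(f"{k:9s}: {v}")
mk = find_mock_ipsp_threshold(p, standard_protocol(p), 50.0, 30.0)
out["mock_ipsp_threshold_mA_cm2"] = mk.g_star
pk = p.replace(gbar_kca=0.0)
mk0 = find_mock_ipsp_threshold(pk, standard_protocol(pk), 50.0, 30.0)
out["mock_ipsp_terminates_without_sk"] = bool(mk0.supra_verdict.terminated)
(OUT / "pharmacology.json").write_text(json.dumps(out, indent=2))
print(f"mock IPSP threshold {mk.g_star:.4g} mA/cm2; still terminates "
      f"without SK: {out['mock_ipsp_terminates_without_sk']}")
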