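"""All-or-none termination threshold of an IPSG delivered mid-plateau.

Bisects the IPSG peak conductance at 50 ms from plateau initiation
(decay tau 10 ms) to a 0.5% bracket and records the duration jump across
it — the hallmark of a saddle-type termination threshold.
"""
import json
from pathlib import Path

from ca1plateau.calibrate import standard_protocol
from ca1plateau.io import write_trace
from ca1plateau.params import calibrated_parameters
from ca1plateau.plateau import find_termination_threshold

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

p = calibrated_parameters()
proto = standard_protocol(p)
th = find_termination_threshold(p, proto, ipsg_onset=50.0, tau_syn=10.0)
sub_d = th.sub_verdict.trial_duration
sup_d = th.supra_verdict.trial_duration
ctrl_d = th.control.duration
out = {"g_star_uS": th.g_star, "bracket_uS": list(th.bracket),
       "control_duration_ms": ctrl_d, "sub_duration_ms": sub_d,
       "supra_duration_ms": sup_d, "jump_ms": sub_d - sup_d,
       "sub_vs_control_pct": 100.0 * (sub_d - ctrl_d) / ctrl_d}
(OUT / "all_or_none.json").write_text(json.dumps(out, indent=2))
write_trace(th.sub_trace, OUT / "just_subthreshold_trace.csv")
write_trace(th.supra_trace, OUT / "just_suprathreshold_trace.csv")
print(f"g* = {th.g_star:.4g} uS; duration drops {sub_d:.1f} -> {sup_d:.1f} ms "
      f"across a {100*(th.bracket[1]-th.bracket[0])/th.bracket[1]:.2f}% "
      f"amplitude interval (control {ctrl_d:.1f} ms)")
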