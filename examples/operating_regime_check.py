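"""Validate the three conditions of the calibrated operating regime.

A usable parameter set must (a) form a bump while a stimulus is on,
(b) fall silent after stimulus offset, and (c) let a weak noisy cue
reignite activity at the most facilitated location. Run this after any
parameter change.
"""
from swmsim import NetworkParams, check_operating_regime

report = check_operating_regime(NetworkParams())
for key, val in report.items():
    print(f"{key:26s} {val}")

ok = report["bump"] and report["silence"] and report["reactivation"]
print("\noperating regime", "OK" if ok else "BROKEN")
print("(peak rates are in the model's dimensionless rate units; the recall")
print("peak is the time-averaged reignited response to the weak cue)")
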