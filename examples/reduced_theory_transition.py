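"""Closed-form transition moments of the reduced group model.

For each item the synaptic efficacy J*u(t)*x(t) relaxes freely during
maintenance; the efficacy difference between the later and the earlier item
flips sign once, at a critical maintenance duration printed below for a
range of depression time constants.
"""
import numpy as np

from swmsim import TheoryParams, delta_jux_two, tc_exact, tc_simplified

base = TheoryParams(u0=0.9, x0=0.1, tau_f=4.0, tau_d=0.3, t_star=1.25, t_b=0.01)

print("tau_d (s)   tc exact (s)   tc simplified+bias (s)")
for tau_d in (0.10, 0.175, 0.25, 0.325, 0.40):
    tp = base.replace(tau_d=tau_d)
    print(f"{tau_d:8.3f}   {tc_exact(tp):12.3f}   {tc_simplified(tp):18.3f}")

tp = base
print(f"\nAt tau_d={tp.tau_d}s the efficacy difference is "
      f"{delta_jux_two(0.1, tp):+.4f} at t=0.1s (earlier item stronger: primacy)")
print(f"and {delta_jux_two(1.5, tp):+.4f} at t=1.5s (later item stronger: recency).")
print("The sign flips exactly at tc; slower depression recovery (larger")
print("tau_d) keeps the earlier item's advantage alive for longer.")
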