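"""One two-item delay-recall trial, phase by phase.

Builds the default network, presents two oriented stimuli in sequence,
waits through a maintenance period and probes recall with a weak noisy cue.
Prints the peak population rate per task phase, the synaptic state left
behind by each item, and the decoded recall orientation.
"""
import numpy as np

from swmsim import (
    GroupTraceRecorder,
    MeanRateAccumulator,
    NetworkParams,
    NetworkState,
    decode_population_vector,
    make_connectivity,
    run_dynamics,
    stimulus_profile,
    two_item_protocol,
)
from swmsim.network import firing_rate
from swmsim.ring import wrap_orientation

params = NetworkParams()
protocol = two_item_protocol(t_maintain=0.3, cued_item=1)
angles = np.deg2rad([-20.0, 18.0])
grid = params.grid()
conn = make_connectivity(params, grid)
rng = np.random.default_rng(0)

masks = np.abs(wrap_orientation(grid.thetas[None, :] - angles[:, None])) \
    <= np.deg2rad(8.0)
groups = GroupTraceRecorder(masks, params, stride=20)

state = NetworkState.resting(params)
phase_start = 0
def phase_peak():
    """Max group rate since the previous phase boundary."""
    global phase_start
    r = groups.group_rate[phase_start:].max() if len(groups._r) > phase_start else 0.0
    phase_start = len(groups._r)
    return float(r)

print(f"{'phase':<10}{'duration':>9}{'peak rate':>11}")
for i, theta in enumerate(angles, start=1):
    spec = protocol.encode_spec.at(theta)
    base = stimulus_profile(spec, grid)
    support = base > 0
    fn = lambda t, g: base + spec.noise_sigma * support * g.standard_normal(base.shape)
    state = run_dynamics(state, fn, protocol.t_encode, params, conn, rng, [groups])
    print(f"encode_{i:<3}{protocol.t_encode:>9.2f}{phase_peak():>11.1f}")
    u_i = state.u[masks[i - 1]].mean()
    x_i = state.x[masks[i - 1]].mean()
    print(f"   item {i} trace at offset: u0={u_i:.2f} x0={x_i:.2f}")
    if i == 1:
        state = run_dynamics(state, None, protocol.t_gap, params, conn, rng, [groups])
        phase_peak()

state = run_dynamics(state, None, protocol.t_maintain, params, conn, rng, [groups])
print(f"{'maintain':<10}{protocol.t_maintain:>9.2f}"
      f"{firing_rate(state.h_e, params.alpha).max():>11.2f}   (activity-silent)")
phase_peak()

cue_center = angles[protocol.cued_item - 1] \
    + protocol.recall_spec.center_jitter * rng.standard_normal()
spec = protocol.recall_spec.at(cue_center)
base = stimulus_profile(spec, grid)
support = base > 0
fn = lambda t, g: base + spec.noise_sigma * support * g.standard_normal(base.shape)
acc = MeanRateAccumulator(state.t + protocol.t_recall / 2,
                          state.t + protocol.t_recall + params.dt, params)
state = run_dynamics(state, fn, protocol.t_recall, params, conn, rng, [acc, groups])
print(f"{'recall':<10}{protocol.t_recall:>9.2f}{acc.profile.max():>11.1f}")

decoded = decode_population_vector(acc.profile, grid)
err = np.rad2deg(wrap_orientation(decoded - angles[protocol.cued_item - 1]))
print(f"\ncued item {protocol.cued_item} at "
      f"{np.rad2deg(angles[protocol.cued_item - 1]):+.1f} deg; "
      f"cue pointed at {np.rad2deg(cue_center):+.1f} deg")
print(f"decoded recall: {np.rad2deg(decoded):+.1f} deg  (error {err:+.1f} deg)")
print("\nSmall error despite the imprecise cue means the reignited bump,")
print("not the cue, carried the memory; the group traces above show the")
print("facilitation (u) left by each item and the depressed resources (x).")
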