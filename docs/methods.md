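# Model and methods

## The network

`swmsim` simulates a one-dimensional continuous-attractor network coding a
pi-periodic orientation θ ∈ [−π/2, π/2). N excitatory units tile the ring;
their synaptic input h_E(θ, t) obeys

    τ dh_E/dt = −h_E + ρ ∫ J(θ, θ′) u(θ′) x(θ′) r_E(θ′) dθ′
                − J_EI r_I + I_ext(θ, t) + I_0 + σ_0 η(θ, t),

with the smoothed threshold-linear rate r = α·ln(1 + e^{h/α}), a
translation-invariant kernel J(θ, θ′) = J·cos[B(θ−θ′)] inside
|B(θ−θ′)| ≤ arccos(−J_0/J) and the floor J_0 < 0 outside, and one global
inhibitory unit τ dh_I/dt = −h_I + J_IE (π/N)Σ r_E whose rate feeds back
subtractively. Each synapse carries short-term plasticity in the
release-probability/resource form:

    du/dt = −u/τ_f + U_0 (1 − u) r,      dx/dt = (1 − x)/τ_d − u x r,

facilitation-dominant (τ_f ≫ τ_d, moderate U_0): a burst of firing leaves
behind elevated u that outlives the depleted x. The instantaneous synaptic
efficacy J·u·x of the neurons tuned to an item is the activity-silent
memory trace everything else in the package is built on.

Integration is explicit Euler–Maruyama (noise scaled by √dt), the simplest
scheme consistent with mean-field rate equations; u and x are clipped to
[0, 1] each step because Euler can overshoot the bounds the continuous
system preserves. Halving dt changes the group efficacy at stimulus offset
by well under 1% at the default dt (checked in the test suite). State
arrays carry an optional leading batch axis, so a whole run of trials
integrates in lock-step through one BLAS-backed matrix product per step.

### Parameters (units, defaults, why)

| parameter | default | meaning / rationale |
|---|---|---|
| N | 180 | one unit per degree of orientation; the recurrent sum (π/N)ρΣ with ρ = N/π makes the collective drive grow with N, so the coupling values below are tied to N = 180 |
| τ | 10 ms | membrane/synaptic time constant, excitatory and inhibitory alike |
| τ_f | 4 s | facilitation decay; centre of the 2–8 s range the sweeps cover |
| τ_d | 0.3 s | depression recovery; centre of 0.1–0.4 s |
| U_0 | 0.3 | per-spike release-probability increment |
| J, J_0 | 1.2, −0.12 | kernel peak and (negative) surround floor, calibrated — see below |
| B | 5.0 | kernel sharpness. The bump half-width must be smaller than the smallest two-item separation (17°); with B = 5 the interaction cutoff arccos(0.1)/5 ≈ 16.9° also keeps one item's encoding from re-exciting the other's group |
| J_EI, J_IE | 2.0, 2.0 | global inhibition loop; strong enough to cap transients and enforce single-bump competition, weak enough to leave cue-driven reignition possible |
| α | 1.5 | rate-function gain |
| I_0 | −5.0 | background drive, far subthreshold: the silent state is stable and baseline facilitation stays negligible |
| σ_0 | 0.1 | background noise; kept small so maintenance-period traces relax freely |
| dt | 0.5 ms | = τ/20 |

### Encoding dynamics are pulsatile

At the calibrated constants an encoding stimulus does not hold a steady
bump for its whole duration: the evoked burst saturates facilitation and
depletes resources within tens of milliseconds, activity collapses, and it
reignites as resources recover — a burst train pinned to the stimulus
position. The stored trace (u near saturation, x near its floor at offset)
is insensitive to the burst phase at the level of run statistics, but
trajectory-level quantities sampled at a single instant inherit a
few-percent dependence on the integration step. The dt-halving convergence
check therefore runs on a smooth subthreshold drive, where the integrator
converges to well below 1%; the experiment-level quantities (recall
statistics, trace crossings) are verified by their agreement with the
closed-form theory instead.

### Calibration

`check_operating_regime` verifies the three conditions a usable parameter
set must satisfy: an encoding stimulus evokes a bump; the network returns
to silence after stimulus offset (no persistent activity — memory is
activity-silent); and a weak noisy recall cue reignites activity at the
most facilitated location. `calibrate_j_peak` scans the kernel peak (floor
scaled along) and returns the midpoint of the widest window satisfying all
three. The shipped defaults are the outcome of that procedure plus one
refinement: the encoding strength (a_encode = 20) was chosen so that the
post-offset bump collapses quickly. With stronger encoding the bump
lingers ~0.2 s after nominal offset, continuing to deplete x, and the
measured efficacy traces then cross visibly later than the reduced theory
(which assumes rates vanish at offset) predicts. At the default strength
the simulated crossing agrees with the closed form to a few percent.

## The task

A trial presents M ∈ {2, 3} oriented stimuli for T_encode = 0.25 s each,
separated by T_gap, waits T_maintain after the last item's offset, then
presents a recall cue for T_recall = 0.2 s. Item orientations: θ_1 uniform;
later items at θ_1 + Δθ with Δθ drawn per item from ±{17, 24, 38, 52, 66,
80}° (two items) or ±{12, 24, 36, 48, 60, 72, 84}° (three items).
External signals are a·cos[B_type(θ−θ_c)] inside |B_type(θ−θ_c)| ≤ π/2 with
white noise of strength σ_type inside the support.

The encoding signal is strong and sharp (a = 20, B = 6, σ = 1). The recall
cue is weak, spatially flat, noisy and *imprecise*:
a = 2 = a_encode/10, B = 1, σ = 4, and its centre errs around the cued
item's true orientation with a per-trial standard deviation of 12°. Each
piece is load-bearing:

- the cue must be weak and flat enough that retrieval is driven by the
  facilitated synapses, not by the cue — a strong or sharp cue pins the
  response on the cued angle and no serial-position structure survives;
- the cue noise supplies the trial-to-trial variability that turns the
  deterministic efficacy ordering into graded recall probabilities;
- the centre jitter means that when the cue *fails* to reignite the trace,
  the decoded response inherits the cue's error (sloppy recall), whereas a
  successful reignition snaps the bump to the stored orientation. Recall
  accuracy thereby becomes a monotone readout of the cued item's synaptic
  efficacy, which is exactly the quantity the theory tracks.

T_recall = 0.2 s is deliberately short relative to τ_d: with a long recall
window the later item's depleted resources recover *inside* the window and
it reignites late, erasing the primacy effect the depleted trace should
produce. Reignition itself is a brief burst — at these STP constants any
reactivated bump depletes its own resources within tens of milliseconds —
so a short window reads out the burst without giving the loser time to
recover. There is no gap after the final item: the maintenance clock
starts at its offset, making the inter-item stride t* = T_encode + T_gap.

The default three-item design uses T_gap = 0.15 s (t* = 0.4 s). The 1–2
transition sits one stride before the 2–3 transition, so it is observable
only when t* is smaller than the transition time itself (~0.6 s here).

## Readout and statistics

The recalled orientation is the population vector θ̂ = ½·arg Σ r_k e^{2iθ_k}
(angles doubled; orientation is π-periodic) of the rate profile averaged
over the last half of the recall window. Profiles with a vanishing
resultant are flagged as guesses, excluded from dispersion statistics and
counted as uniform responses in the target probability.

Per item, the normalized target probability P is obtained by fitting, by
EM, a mixture over doubled response deviations: a von Mises component at
the target, one at each non-target, and a uniform component, all sharing
one concentration κ; P is the mean posterior probability of the target
component over that item's trials. Circular variance (1 − R̄) and circular
kurtosis ((ρ_2 cos(μ_2 − 2μ_1) − R̄⁴)/(1 − R̄)²) are computed on doubled
errors. Per-run P values are compared across serial positions with a
two-sided paired Wilcoxon signed-rank test (P values are bounded
proportions; a t-test's normality assumption is unattractive), mapped to
the usual n.s. / * / ** / *** categories.

The empirical transition moment T_c is the linearly interpolated zero
crossing of the mean P difference across maintenance durations. Mean
differences smaller than 2×10⁻³ (a couple of posterior units at desk
scale) count as zero: when both items are recalled near-perfectly the
difference curve carries a plateau of numerical dust, and the crossing is
taken at the first plateau sample after the negative branch. The same
linear interpolation on the trial-averaged efficacy difference gives
T_c′(SIM). Circular kurtosis becomes numerically unstable when recall
saturates (R̄ → 1 puts a vanishing denominator in its definition), so its
crossing is reported but treated as the least reliable of the three.

## Reduced theory

During maintenance rates are ≈ 0, so each group relaxes independently:
u(t) = u_0 e^{−t/τ_f}, x(t) = 1 − (1 − x_0)e^{−t/τ_d}, with (u_0, x_0) the
group state at its stimulus offset (equal across items, since all items are
encoded identically). The efficacy difference between a later and an
earlier item is built constructively as Jux(t) − Jux(t + t*); its single
zero crossing has the closed form

    T = τ_d · ln[ (1 − x_0)(1 − e^{−t*/τ_d − t*/τ_f}) / (1 − e^{−t*/τ_f}) ],

non-decreasing in τ_f and τ_d, non-increasing in t*, with a NaN return as
the explicit no-crossing indicator (x_0 → 1: recency from the start). A
simplified form drops the e^{−t*/τ_d} factor (valid when t* spans several
τ_d) and adds a constant cue-response bias t_b ∈ (0, T_recall], default τ.
For three items the shift relation Jux_i(t) = Jux_j(t + (j−i)t*) gives
T′_c12 = T′_c23 − t*: the earlier pair's transition leads by exactly one
stride. Theory/simulation comparisons use (u_0, x_0) measured from the
simulated group traces at the stimulus offsets (`estimate_u0_x0`).

## Desk scale, determinism, limitations

Experiments default to 10 runs × 60 trials per maintenance duration (the
published design is 50 × 300 for two items and 50 × 500 for three; the
full scale is available via `ExperimentPlan.paper_scale`). The two-item
maintenance grid spans 0.25–4.5× the theoretical transition: the recency
effect peaks near 4–5× the transition and fades beyond as both traces
decay. The three-item grid brackets both pairwise transitions. Group
half-width for trace measurement is 8°, comfortably inside the smallest
item separation.

Child seeds derive from the root seed and the (condition, run) labels via
`numpy.random.SeedSequence`, so any execution order — or a rerun from the
JSON manifest every experiment writes — reproduces byte-identical CSVs.
Trials within a run share one generator (the run is integrated as a single
batch); runs are the unit of independent reproducibility.

What the simulated conditions do not capture: participants differ only by
RNG seed (no parameter heterogeneity); the recall cue's spatial form and
imprecision are design choices standing in for an unspecified
psychophysical cue; encoding leaves near-saturated facilitation
(u_0 ≈ 0.97), so the facilitation side of the trace contrast is compressed
relative to a lower-gain regime; and with three items the smallest
separation (12°) lets neighbouring groups interact, which the reduced
theory ignores. The 1–2 pairwise contrast in the three-item task is
intrinsically weak (adjacent traces differ by only e^{t*/τ_f} ≈ 8% in u at
the short stride), so its empirical transition estimate carries much more
sampling noise than the 2–3 one at desk scale.
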