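"""Ring attractor network with short-term facilitation and depression.

The excitatory population h_E(theta, t) lives on an orientation ring and is
recurrently coupled through a translation-invariant cosine kernel whose
instantaneous strength is gated by the synaptic variables u (release
probability, facilitation) and x (available resources, depression). A single
global inhibitory pool h_I(t) integrates total ring activity and feeds back
subtractively, enforcing competition so that only one activity bump survives
at a time.

Dynamics (explicit Euler-Maruyama, step dt):

    tau dh_E = [-h_E + (pi/N) rho sum_k J(theta,theta_k) u_k x_k r_k
                - J_EI r_I + I_ext + I0] dt + sigma0 sqrt(dt) eta
    tau dh_I = [-h_I + J_IE (pi/N) sum_k r_k] dt
    du      = [-u/tau_f + U0 (1-u) r] dt
    dx      = [(1-x)/tau_d - u x r] dt

with r = alpha*log(1+exp(h/alpha)) and u, x clipped to [0, 1] after each
step (Euler can overshoot the bounds the continuous system preserves).

All state arrays may carry leading batch dimensions, in which case every
batch entry is an independent trial integrated in lock-step; this is how the
experiment layer simulates a run's worth of trials at once.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import NetworkParams
from .ring import RingGrid, wrap_orientation

__all__ = [
    "NetworkState",
    "IntegrationBlowupError",
    "make_connectivity",
    "firing_rate",
    "step",
    "run_dynamics",
    "TraceRecorder",
    "GroupTraceRecorder",
    "MeanRateAccumulator",
    "check_operating_regime",
    "calibrate_j_peak",
]


class IntegrationBlowupError(RuntimeError):
    """Raised when the Euler integration produces non-finite state."""


@dataclass
class NetworkState:
    """Time-indexed network state; arrays may have leading batch dims."""

    h_e: np.ndarray   # (..., N) synaptic input to excitatory ring
    h_i: np.ndarray   # (...,)   synaptic input to the inhibitory pool
    u: np.ndarray     # (..., N) release probability, in [0, 1]
    x: np.ndarray     # (..., N) available resources, in [0, 1]
    t: float = 0.0

    @classmethod
    def resting(cls, params: NetworkParams, batch_shape: tuple = ()) -> "NetworkState":
        """Silent resting state: h_E at the background drive, u=0, x=1."""
        n = params.n_neurons
        return cls(
            h_e=np.full(batch_shape + (n,), params.i0, dtype=float),
            h_i=np.zeros(batch_shape, dtype=float),
            u=np.zeros(batch_shape + (n,), dtype=float),
            x=np.ones(batch_shape + (n,), dtype=float),
            t=0.0,
        )

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.h_e.copy(), self.h_i.copy(), self.u.copy(), self.x.copy(), self.t
        )

    def rates(self, params: NetworkParams) -> np.ndarray:
        return firing_rate(self.h_e, params.alpha)


def firing_rate(h, alpha: float):
    """Smoothed threshold-linear rate r = alpha*log(1+exp(h/alpha)).

    Overflow-safe: for large h it returns h + alpha*log1p(exp(-h/alpha))
    which tends to h, and for very negative h it tends to 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    z = np.asarray(h, dtype=float) / alpha
    # softplus(z) computed on the stable branch of |z|
    out = alpha * (np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z))))
    return out


def make_connectivity(params: NetworkParams, grid: RingGrid | None = None) -> np.ndarray:
    """Translation-invariant ring kernel J(theta, theta').

    Entry (i, j) is J*cos[B*(theta_i - theta_j)] while the scaled wrapped
    difference lies within +-arccos(-J0/J), and the floor J0 beyond that
    cutoff. The matrix is symmetric and circulant.
    """
    if grid is None:
        grid = params.grid()
    ratio = -params.j_floor / params.j_peak
    if abs(ratio) > 1.0:
        raise ValueError(
            "arccos(-j_floor/j_peak) undefined: "
            f"|j_floor/j_peak| = {abs(ratio):.3f} > 1"
        )
    cutoff = np.arccos(ratio)
    diff = wrap_orientation(grid.thetas[:, None] - grid.thetas[None, :])
    arg = params.b_width * diff
    return np.where(np.abs(arg) <= cutoff, params.j_peak * np.cos(arg), params.j_floor)


def step(
    state: NetworkState,
    ext_input,
    params: NetworkParams,
    connectivity: np.ndarray,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Advance the network by one Euler-Maruyama step of size dt.

    ``ext_input`` is the external drive over the ring (broadcastable to
    h_e's shape); pass 0 for no input. ``rng=None`` disables the background
    noise term regardless of sigma0 (useful for deterministic checks).
    """
    p = params
    n = p.n_neurons
    dt, tau = p.dt, p.tau

    r_e = firing_rate(state.h_e, p.alpha)
    r_i = firing_rate(state.h_i, p.alpha)

    # discretized recurrent integral: (pi/N) * rho * sum_k J(.,k) u_k x_k r_k
    pref = (np.pi / n) * p.rho
    rec = pref * ((state.u * state.x * r_e) @ connectivity.T)

    drive = -state.h_e + rec - p.j_ei * r_i[..., None] + ext_input + p.i0
    h_e = state.h_e + (dt / tau) * drive
    if rng is not None and p.sigma0 > 0.0:
        h_e += (p.sigma0 * np.sqrt(dt) / tau) * rng.standard_normal(state.h_e.shape)

    h_i = state.h_i + (dt / tau) * (
        -state.h_i + p.j_ie * (np.pi / n) * r_e.sum(axis=-1)
    )

    u = state.u + dt * (-state.u / p.tau_f + p.u_increment * (1.0 - state.u) * r_e)
    x = state.x + dt * ((1.0 - state.x) / p.tau_d - state.u * state.x * r_e)
    np.clip(u, 0.0, 1.0, out=u)
    np.clip(x, 0.0, 1.0, out=x)

    if not np.isfinite(np.sum(h_e)):
        raise IntegrationBlowupError(
            f"non-finite state at t={state.t + dt:.4f}s "
            f"(max |h_E| = {np.nanmax(np.abs(h_e)):.3g})"
        )
    return NetworkState(h_e=h_e, h_i=h_i, u=u, x=x, t=state.t + dt)


# ---------------------------------------------------------------------------
# recorders


class TraceRecorder:
    """Record raw state fields every ``stride`` steps (plus the initial sample).

    ``fields`` is a subset of {"h_e", "h_i", "r_e", "u", "x", "jux"}; "jux"
    is the instantaneous synaptic efficacy J*u*x over the full ring.
    """

    _KNOWN = ("h_e", "h_i", "r_e", "u", "x", "jux")

    def __init__(self, fields=("r_e", "u", "x"), stride: int = 20,
                 params: NetworkParams | None = None):
        unknown = set(fields) - set(self._KNOWN)
        if unknown:
            raise ValueError(f"unknown trace fields: {sorted(unknown)}")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        if ("r_e" in fields or "jux" in fields) and params is None:
            raise ValueError("derived fields need params")
        self.fields = tuple(fields)
        self.stride = int(stride)
        self.params = params
        self._samples: dict[str, list] = {f: [] for f in self.fields}
        self._times: list[float] = []

    def _sample(self, state: NetworkState) -> None:
        for f in self.fields:
            if f == "r_e":
                val = firing_rate(state.h_e, self.params.alpha)
            elif f == "jux":
                val = self.params.j_peak * state.u * state.x
            else:
                val = getattr(state, f).copy()
            self._samples[f].append(val)
        self._times.append(state.t)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self._times)

    @property
    def traces(self) -> dict[str, np.ndarray]:
        """Stacked traces keyed by field; time is the first axis."""
        return {f: np.stack(v) if v else np.empty((0,)) for f, v in self._samples.items()}


class GroupTraceRecorder:
    """Record group-averaged r, u, x and efficacy J*u*x for item groups.

    ``masks`` is boolean with shape (M, N) or (batch..., M, N): membership of
    each neuronal group (neurons within the group half-width of an item's
    orientation). Group means use 1/m_i weighting over members.
    """

    def __init__(self, masks: np.ndarray, params: NetworkParams, stride: int = 20):
        masks = np.asarray(masks, dtype=float)
        counts = masks.sum(axis=-1, keepdims=True)
        if np.any(counts == 0):
            raise ValueError("empty neuronal group: widen half_width or refine grid")
        self.weights = masks / counts
        self.params = params
        self.stride = int(stride)
        self._r, self._u, self._x, self._ux, self._times = [], [], [], [], []

    def _sample(self, state: NetworkState) -> None:
        w = self.weights
        r_e = firing_rate(state.h_e, self.params.alpha)
        self._r.append(np.einsum("...mn,...n->...m", w, r_e))
        self._u.append(np.einsum("...mn,...n->...m", w, state.u))
        self._x.append(np.einsum("...mn,...n->...m", w, state.x))
        self._ux.append(np.einsum("...mn,...n->...m", w, state.u * state.x))
        self._times.append(state.t)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self._times)

    @property
    def group_rate(self) -> np.ndarray:
        """r_i(t), time axis first."""
        return np.stack(self._r)

    @property
    def group_u(self) -> np.ndarray:
        return np.stack(self._u)

    @property
    def group_x(self) -> np.ndarray:
        return np.stack(self._x)

    @property
    def group_jux(self) -> np.ndarray:
        """Jux_i(t) = (J/m_i) * sum_{G_i} u*x, time axis first.

        Averages the product u*x over group members, not the product of the
        group averages.
        """
        return self.params.j_peak * np.stack(self._ux)


class MeanRateAccumulator:
    """Accumulate the mean firing-rate profile over a time window.

    Samples every step with t in [t_start, t_end); used to decode the
    recall response from the time-averaged profile.
    """

    stride = 1

    def __init__(self, t_start: float, t_end: float, params: NetworkParams):
        if not t_end > t_start:
            raise ValueError("empty accumulation window")
        self.t_start, self.t_end = float(t_start), float(t_end)
        self.params = params
        self._sum = 0.0
        self._count = 0

    def _sample(self, state: NetworkState) -> None:
        # called every step; accept only samples inside the window
        if self.t_start <= state.t < self.t_end:
            self._sum = self._sum + firing_rate(state.h_e, self.params.alpha)
            self._count += 1

    @property
    def profile(self) -> np.ndarray:
        if self._count == 0:
            raise ValueError("accumulation window saw no samples")
        return self._sum / self._count


def run_dynamics(
    state: NetworkState,
    input_fn,
    duration: float,
    params: NetworkParams,
    connectivity: np.ndarray,
    rng: np.random.Generator | None = None,
    recorders=(),
) -> NetworkState:
    """Integrate the network for ``duration`` seconds from ``state``.

    ``input_fn(t, rng)`` returns the external drive for the step taken at
    clock time t (or None for no input). Recorders receive the initial state
    and then every ``recorder.stride`` steps. Bit-reproducible given the
    same (seeded) generator, state, parameters and schedule.

    Returns the final state; recorded traces live on the recorder objects.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    n_steps = int(round(duration / params.dt))
    for rec in recorders:
        rec._sample(state)
    for i in range(n_steps):
        ext = input_fn(state.t, rng) if input_fn is not None else 0.0
        if ext is None:
            ext = 0.0
        state = step(state, ext, params, connectivity, rng)
        for rec in recorders:
            if (i + 1) % rec.stride == 0:
                rec._sample(state)
    return state


# ---------------------------------------------------------------------------
# operating-regime check and calibration


def _bump_stats(state: NetworkState, params: NetworkParams) -> tuple[float, float]:
    r = firing_rate(state.h_e, params.alpha)
    return float(np.max(r)), float(np.mean(r))


def check_operating_regime(
    params: NetworkParams,
    a_encode: float = 20.0,
    b_encode: float = 6.0,
    a_recall: float = 2.0,
    b_recall: float = 1.0,
    recall_noise: float = 4.0,
    t_encode: float = 0.25,
    t_settle: float = 1.0,
    t_recall: float = 0.2,
    rate_floor: float = 1.0,
    seed: int = 0,
    verbose: bool = False,
) -> dict:
    """Check the three conditions of the working regime.

    (a) an encoding stimulus evokes an activity bump,
    (b) the network decays back to silence after stimulus offset
        (checked noise-free), and
    (c) the weak noisy recall cue re-ignites activity at the facilitated
        location (reignition is noise-assisted, so this phase runs with the
        seeded cue noise; the burst is detected on the time-averaged rate).

    Returns a dict with booleans ``bump``, ``silence``, ``reactivation`` and
    the measured peak rates. Used by :func:`calibrate_j_peak` and shipped so
    users can re-validate after changing parameters.
    """
    from .protocol import StimulusSpec, stimulus_profile  # local import: avoid cycle

    grid = params.grid()
    conn = make_connectivity(params, grid)
    quiet = params.replace(sigma0=0.0)

    state = NetworkState.resting(quiet)
    enc = stimulus_profile(
        StimulusSpec(amplitude=a_encode, sharpness=b_encode, center=0.0), grid
    )
    enc_rec = TraceRecorder(("r_e",), stride=5, params=quiet)
    state = run_dynamics(state, lambda t, g: enc, t_encode, quiet, conn,
                         recorders=[enc_rec])
    # encoding can be pulsatile (depletion quenches and reignites the bump),
    # so judge the response by its maximum over the interval
    peak_during = float(enc_rec.traces["r_e"].max())
    bump_ok = peak_during > max(5.0, 2.0 * rate_floor)

    state = run_dynamics(state, None, t_settle, quiet, conn)
    peak_after, _ = _bump_stats(state, quiet)
    silence_ok = peak_after < rate_floor

    # recall: noisy weak cue at the facilitated location; average the rate
    # profile over the whole window so a transient burst is caught
    rng = np.random.default_rng(seed)
    cue = stimulus_profile(
        StimulusSpec(amplitude=a_recall, sharpness=b_recall, center=0.0), grid
    )
    support = cue > 0
    def cue_fn(t, g):
        return cue + recall_noise * support * g.standard_normal(cue.shape)
    acc = MeanRateAccumulator(state.t, state.t + t_recall + params.dt, params)
    state = run_dynamics(state, cue_fn, t_recall, params, conn, rng,
                         recorders=[acc])
    profile = acc.profile
    peak_recall = float(np.max(profile))
    peak_idx = int(np.argmax(profile))
    # reignited activity should sit near the facilitated location theta=0
    loc_err = abs(wrap_orientation(grid.thetas[peak_idx]))
    react_ok = peak_recall > rate_floor and loc_err < np.pi / 12
    out = {
        "bump": bool(bump_ok),
        "silence": bool(silence_ok),
        "reactivation": bool(react_ok),
        "peak_rate_encode": peak_during,
        "peak_rate_after_settle": peak_after,
        "peak_rate_recall": peak_recall,
        "recall_peak_offset": float(loc_err),
    }
    if verbose:
        print(out)
    return out


def calibrate_j_peak(
    params: NetworkParams,
    lo: float = 0.05,
    hi: float = 2.0,
    n_grid: int = 16,
    **regime_kwargs,
) -> tuple[float, dict]:
    """Scan j_peak (with j_floor scaled proportionally) for the working regime.

    Returns the midpoint of the widest contiguous j_peak window where all
    three :func:`check_operating_regime` conditions hold, plus the regime
    report at that value. Raises if no window exists.
    """
    floor_ratio = params.j_floor / params.j_peak
    grid_vals = np.linspace(lo, hi, n_grid)
    ok = np.zeros(n_grid, dtype=bool)
    reports = []
    for k, j in enumerate(grid_vals):
        p = params.replace(j_peak=float(j), j_floor=float(j * floor_ratio))
        rep = check_operating_regime(p, **regime_kwargs)
        reports.append(rep)
        ok[k] = rep["bump"] and rep["silence"] and rep["reactivation"]
    if not ok.any():
        raise RuntimeError("no j_peak in the scanned range satisfies the regime")
    # widest contiguous True window
    best_len, best_mid = 0, None
    start = None
    for k, flag in enumerate(list(ok) + [False]):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            if k - start > best_len:
                best_len, best_mid = k - start, (start + k - 1) // 2
            start = None
    j_star = float(grid_vals[best_mid])
    return j_star, reports[best_mid]
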