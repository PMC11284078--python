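"""Reduced model of the primacy-to-recency transition.

During maintenance the ring is silent (rates ~ 0), so each item's neuronal
group relaxes independently: its release probability decays as
u(t) = u0*exp(-t/tau_f) and its resources recover as
x(t) = 1-(1-x0)*exp(-t/tau_d), where (u0, x0) are the values at that item's
stimulus offset. The group's synaptic efficacy is Jux(t) = J*u(t)*x(t): it
first rises (resources recover faster than facilitation decays), peaks, and
then decays — so an item presented t* = t_encode + t_gap earlier is ahead on
this curve. The sign of the efficacy difference between a later and an
earlier item therefore flips exactly once, from negative (primacy: the
earlier item's trace is stronger) to positive (recency), at a critical
maintenance duration obtained in closed form below. Functions are
vectorized over parameter grids; a NaN return is the explicit
"no crossing in the maintenance period" indicator.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TheoryParams",
    "stp_relax",
    "jux_group",
    "delta_jux_two",
    "tc_exact",
    "tc_simplified",
    "tc_three_items",
    "estimate_u0_x0",
]


@dataclass(frozen=True)
class TheoryParams:
    """Constants of the reduced group model.

    u0, x0: facilitation and resource levels at a group's stimulus offset
    (assumed equal across groups — all items are encoded with the same
    strength and duration). t_star is the inter-item stride
    t_encode + t_gap; t_b a small constant accounting for the time the
    recall cue needs to re-ignite a group (of order the membrane time
    constant, default 10 ms).
    """

    u0: float
    x0: float
    tau_f: float = 4.0
    tau_d: float = 0.3
    t_star: float = 1.25
    t_b: float = 0.01
    j_peak: float = 1.0

    def __post_init__(self):
        # fields may be numpy arrays (vectorized parameter grids)
        if not (np.all(np.greater(self.tau_f, self.tau_d))
                and np.all(np.greater(self.tau_d, 0))):
            raise ValueError("require tau_f > tau_d > 0")
        if not np.all(np.greater(self.t_star, 0)):
            raise ValueError("t_star must be > 0")
        if not (np.all(np.greater(self.u0, 0)) and np.all(np.less_equal(self.u0, 1))):
            raise ValueError("u0 must lie in (0, 1]")
        if not (np.all(np.greater_equal(self.x0, 0))
                and np.all(np.less_equal(self.x0, 1))):
            raise ValueError("x0 must lie in [0, 1]")

    def replace(self, **changes) -> "TheoryParams":
        return replace(self, **changes)


def stp_relax(u0, x0, t, tau_f: float, tau_d: float):
    """Closed-form relaxation of (u, x) at zero firing rate.

    u decays to 0 with tau_f, x recovers to 1 with tau_d.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    u = u0 * np.exp(-t / tau_f)
    x = 1.0 - (1.0 - x0) * np.exp(-t / tau_d)
    return u, x


def jux_group(t, params: TheoryParams):
    """Synaptic efficacy J*u(t)*x(t) of one group, clock from its own offset."""
    u, x = stp_relax(params.u0, params.x0, t, params.tau_f, params.tau_d)
    return params.j_peak * u * x


def delta_jux_two(t, params: TheoryParams):
    """Efficacy difference Jux_2(t) - Jux_1(t), two items, clock from item-2 offset.

    Built constructively from :func:`jux_group`: item 1's own clock is ahead
    by t_star. Negative values mean the first item's trace is stronger
    (primacy regime), positive the second's (recency).
    """
    t = np.asarray(t, dtype=float)
    return jux_group(t, params) - jux_group(t + params.t_star, params)


def _log_argument(params: TheoryParams, with_depression_factor: bool):
    ts, tf, td = params.t_star, params.tau_f, params.tau_d
    denom = 1.0 - np.exp(-ts / tf)
    num = 1.0 - params.x0
    if with_depression_factor:
        num = num * (1.0 - np.exp(-ts / td - ts / tf))
    return num / denom


def tc_exact(params: TheoryParams):
    """Closed-form zero crossing of :func:`delta_jux_two`.

    T = tau_d * ln[ (1-x0)(1-e^{-t*/tau_d - t*/tau_f}) / (1-e^{-t*/tau_f}) ].

    Returns NaN when the argument of the logarithm is <= 1, i.e. when the
    crossing would fall at or before maintenance onset (recency from the
    start; the x0 -> 1 limit). Vectorizes over array-valued fields.
    """
    arg = _log_argument(params, with_depression_factor=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = params.tau_d * np.log(arg)
    t = np.where(arg <= 1.0, np.nan, t)
    return float(t) if np.ndim(t) == 0 else t

def tc_simplified(params: TheoryParams):
    """Simplified crossing time for tau_f >> tau_d, plus the cue-response bias.

    T = tau_d * ln[(1-x0)/(1-e^{-t*/tau_f})] + t_b. The dropped factor
    e^{-t*/tau_d} is negligible when the stride t* is several tau_d.
    """
    arg = _log_argument(params, with_depression_factor=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = params.tau_d * np.log(arg) + params.t_b
    t = np.where(arg <= 0.0, np.nan, t)
    return float(t) if np.ndim(t) == 0 else t


def tc_three_items(params: TheoryParams, t_b12: float | None = None,
                   t_b23: float | None = None):
    """Critical moments for three sequential items.

    The shift relation Jux_i(t) = Jux_j(t + (j-i) t*) (shared last-item
    clock) makes the 1-2 crossing an exact copy of the 2-3 crossing shifted
    earlier by one stride:

        Tc'_12 = tau_d*ln[(1-x0)/(1-e^{-t*/tau_f})] - t* + t_b12
        Tc'_23 = tau_d*ln[(1-x0)/(1-e^{-t*/tau_f})]       + t_b23

    With equal biases Tc'_12 = Tc'_23 - t* < Tc'_23: the primacy advantage
    of item 1 over item 2 is lost a full stride before item 3 overtakes
    item 2.
    """
    if t_b12 is None:
        t_b12 = params.t_b
    if t_b23 is None:
        t_b23 = params.t_b
    base = tc_simplified(params.replace(t_b=0.0))
    return base - params.t_star + t_b12, base + t_b23


def estimate_u0_x0(group_u, group_x, times, offset_times):
    """Read (u0, x0) per group from simulated group traces at stimulus offsets.

    ``group_u``/``group_x`` have time on the first axis (any batch axes
    after it, groups last); ``offset_times[i]`` is item i's stimulus-offset
    time on the same clock as ``times``. Trailing batch axes are averaged.

    Returns (u0, x0) arrays of shape (n_groups,).
    """
    times = np.asarray(times)
    group_u = np.asarray(group_u)
    group_x = np.asarray(group_x)
    offset_times = np.atleast_1d(offset_times)
    if np.any(offset_times < times[0] - 1e-9) or np.any(offset_times > times[-1] + 1e-9):
        raise ValueError("stimulus offset outside the recorded trace")
    u0 = np.empty(len(offset_times))
    x0 = np.empty(len(offset_times))
    for i, t_off in enumerate(offset_times):
        k = int(np.argmin(np.abs(times - t_off)))
        u_slice = group_u[k, ..., i]
        x_slice = group_x[k, ..., i]
        u0[i] = float(np.mean(u_slice))
        x0[i] = float(np.mean(x_slice))
    return u0, x0
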