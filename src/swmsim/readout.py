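"""Everything downstream of raw traces: decoding and recall statistics.

Responses are orientations, i.e. pi-periodic: all circular statistics and
the von Mises mixture operate on doubled angles (period pi -> 2pi), and
every reported error is un-doubled back to the orientation scale.

The per-item recall performance P_i is the "normalized target probability":
responses of trials cueing item i are modelled as a mixture of a von Mises
component at the target orientation, one at each non-target, and a uniform
guess component (shared concentration kappa, weights fitted by EM); P_i is
the mean posterior probability of the target component across those trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .ring import RingGrid, wrap_orientation

__all__ = [
    "GroupConfig",
    "UndecodableProfileError",
    "group_efficacy",
    "decode_population_vector",
    "recall_angle",
    "MixtureFit",
    "normalized_target_probability",
    "circular_variance",
    "circular_kurtosis",
    "compare_conditions",
    "significance_category",
    "first_zero_crossing",
    "empirical_tc",
    "empirical_tc_prime",
    "generate_synthetic_responses",
]


class UndecodableProfileError(ValueError):
    """Raised when a rate profile carries no directional signal."""


@dataclass(frozen=True)
class GroupConfig:
    """Neuronal groups: neurons within ``half_width`` of each item orientation."""

    group_centers: tuple
    half_width: float = np.deg2rad(15.0)

    def __post_init__(self):
        object.__setattr__(
            self, "group_centers", tuple(float(c) for c in np.atleast_1d(self.group_centers))
        )
        if not (0.0 < self.half_width < np.pi / 4):
            raise ValueError("half_width must lie in (0, pi/4)")

    def masks(self, grid: RingGrid) -> np.ndarray:
        """Boolean membership masks, shape (n_groups, N)."""
        centers = np.asarray(self.group_centers)
        d = np.abs(wrap_orientation(grid.thetas[None, :] - centers[:, None]))
        m = d <= self.half_width
        if np.any(m.sum(axis=1) == 0):
            raise ValueError("empty neuronal group: widen half_width or refine grid")
        return m


def group_efficacy(u_trace, x_trace, grid: RingGrid, groups: GroupConfig,
                   j_peak: float):
    """Group synaptic efficacies Jux_i(t) and pairwise differences.

    ``u_trace``/``x_trace`` have shape (T, N) (time first). Returns
    ``(jux, delta)`` where jux has shape (T, M) and ``delta[(i, j)]`` (for
    0-based i < j) is Jux_j - Jux_i: positive means the later item's trace
    is stronger.
    """
    u_trace = np.asarray(u_trace)
    x_trace = np.asarray(x_trace)
    masks = groups.masks(grid)
    weights = masks / masks.sum(axis=1, keepdims=True)
    jux = j_peak * (u_trace * x_trace) @ weights.T
    m = len(groups.group_centers)
    delta = {
        (i, j): jux[..., j] - jux[..., i] for i in range(m) for j in range(i + 1, m)
    }
    return jux, delta


def decode_population_vector(rate_profile, grid: RingGrid,
                             rel_tol: float = 1e-8) -> float:
    """Population-vector estimate of the encoded orientation.

    theta_hat = (1/2) arg sum_k r_k exp(2i theta_k), wrapped to
    [-pi/2, pi/2). Angles are doubled because orientation is pi-periodic.
    Raises :class:`UndecodableProfileError` for an all-zero or (near-)
    uniform profile, whose resultant vanishes.
    """
    r = np.asarray(rate_profile, dtype=float)
    total = np.sum(np.abs(r))
    if not total > 0:
        raise UndecodableProfileError("all-zero rate profile")
    z = np.sum(r * np.exp(2j * grid.thetas))
    if np.abs(z) < rel_tol * total:
        raise UndecodableProfileError("vanishing population resultant")
    return float(wrap_orientation(0.5 * np.angle(z)))


def recall_angle(r_trace, times, recall_window, grid: RingGrid) -> float:
    """Decode the recalled orientation from the tail of the recall window.

    Averages the rate profile over the last half of ``recall_window``
    (a (t_start, t_end) pair on the same clock as ``times``) and decodes it
    with the population vector. ``r_trace`` has shape (T, N).
    """
    t0, t1 = recall_window
    if not t1 > t0:
        raise ValueError("empty recall window")
    times = np.asarray(times)
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError("recall window outside the recorded trace")
    sel = (times >= (t0 + t1) / 2.0) & (times <= t1 + 1e-12)
    profile = np.asarray(r_trace)[sel].mean(axis=0)
    return decode_population_vector(profile, grid)


# ---------------------------------------------------------------------------
# von Mises mixture ("normalized target probability")


def _vm_logpdf(phi, kappa):
    # log von Mises density on doubled angles, using the scaled Bessel i0e
    # for overflow safety: log I0(k) = log(i0e(k)) + k
    return kappa * np.cos(phi) - (np.log(2 * np.pi) + np.log(special.i0e(kappa)) + kappa)


def _a1inv(r):
    """Invert the Bessel ratio A1(kappa)=I1/I0 (Fisher's approximation)."""
    if r >= 1.0:
        return 1e3
    if r <= 0.0:
        return 1e-3
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    return float(np.clip(k, 1e-3, 1e3))


@dataclass
class MixtureFit:
    """Result of the target/non-target/uniform mixture fit for one item."""

    p_target: float           # mean posterior of the target component
    kappa: float              # shared von Mises concentration (doubled angles)
    weights: np.ndarray       # (target, *non-targets, uniform), sums to 1
    converged: bool
    fallback: bool            # True if EM failed and nearest-item assignment was used
    posteriors: np.ndarray = field(repr=False)  # (n_trials, n_components)
    log_likelihood: float = np.nan
    n_guess_trials: int = 0


def normalized_target_probability(
    errors_to_target,
    errors_to_nontargets=None,
    n_guess_trials: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> MixtureFit:
    """Fit the response mixture for one item and return P (target posterior).

    ``errors_to_target``: wrapped response-minus-target orientation errors,
    shape (n,). ``errors_to_nontargets``: wrapped response-minus-nontarget
    errors, shape (n, k) with k >= 0 non-target items. ``n_guess_trials``
    counts undecodable trials: they are excluded from the fit but enter P's
    denominator with target posterior 0 (they are uniform guesses by
    construction).

    Components share a single concentration; weights and kappa are fitted
    by EM. A non-convergent or degenerate fit falls back to nearest-item
    assignment proportions, flagged via ``fallback``.
    """
    err_t = np.asarray(errors_to_target, dtype=float)
    n = err_t.size
    if n + n_guess_trials < 20:
        raise ValueError("need at least 20 trials per item")
    if n == 0:
        # every trial was a retrieval failure: pure guessing, P = 0
        return MixtureFit(
            p_target=0.0, kappa=np.nan, weights=np.array([0.0, 1.0]),
            converged=True, fallback=False, posteriors=np.empty((0, 2)),
            n_guess_trials=n_guess_trials,
        )
    if errors_to_nontargets is None:
        err_nt = np.empty((n, 0))
    else:
        err_nt = np.asarray(errors_to_nontargets, dtype=float).reshape(n, -1)
    k_nt = err_nt.shape[1]
    n_comp = 1 + k_nt + 1  # target, non-targets, uniform

    # doubled deviations per component
    phi = np.concatenate([err_t[:, None], err_nt], axis=1) * 2.0  # (n, 1+k_nt)

    weights = np.full(n_comp, np.nan)
    weights[0] = 0.6
    if k_nt:
        weights[1:-1] = 0.3 / k_nt
        weights[-1] = 0.1
    else:
        weights[-1] = 0.4
    kappa = 5.0
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        log_parts = np.empty((n, n_comp))
        log_parts[:, :-1] = _vm_logpdf(phi, kappa)
        log_parts[:, -1] = -np.log(2 * np.pi)
        log_parts = log_parts + np.log(weights)
        norm = special.logsumexp(log_parts, axis=1)
        gamma = np.exp(log_parts - norm[:, None])  # (n, n_comp)
        ll = float(np.sum(norm))

        weights = gamma.mean(axis=0)
        weights = np.clip(weights, 1e-12, None)
        weights = weights / weights.sum()
        w_vm = gamma[:, :-1]
        denom = w_vm.sum()
        if denom > 1e-12:
            rbar = float(np.sum(w_vm * np.cos(phi)) / denom)
            kappa = _a1inv(rbar)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    if not converged and not np.isfinite(ll_old):
        # degenerate fit: nearest-item assignment proportion, flagged
        all_err = np.abs(np.concatenate([err_t[:, None], err_nt], axis=1))
        nearest = np.argmin(all_err, axis=1)
        gamma = np.zeros((n, n_comp))
        gamma[np.arange(n), nearest] = 1.0
        p = (np.sum(nearest == 0)) / (n + n_guess_trials)
        return MixtureFit(
            p_target=float(p), kappa=np.nan, weights=gamma.mean(axis=0),
            converged=False, fallback=True, posteriors=gamma,
            n_guess_trials=n_guess_trials,
        )

    p_target = float(gamma[:, 0].sum() / (n + n_guess_trials))
    return MixtureFit(
        p_target=p_target, kappa=float(kappa), weights=weights,
        converged=converged, fallback=False, posteriors=gamma,
        log_likelihood=ll_old, n_guess_trials=n_guess_trials,
    )


# ---------------------------------------------------------------------------
# circular statistics (doubled angles, CircStat conventions)


def _trig_moments(phi):
    z1 = np.mean(np.exp(1j * phi))
    z2 = np.mean(np.exp(2j * phi))
    return z1, z2


def circular_variance(errors) -> float:
    """CV = 1 - mean resultant length of the doubled errors; in [0, 1]."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("need at least 2 samples")
    z1, _ = _trig_moments(2.0 * errors)
    return float(1.0 - np.abs(z1))


def circular_kurtosis(errors) -> float:
    """Circular kurtosis k = (rho2*cos(mu2 - 2*mu1) - Rbar^4) / (1 - Rbar)^2.

    Computed on doubled errors; mu1/mu2 are the first/second trigonometric
    moment directions, rho2 the second-moment resultant length.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("need at least 2 samples")
    z1, z2 = _trig_moments(2.0 * errors)
    rbar = np.abs(z1)
    mu1 = np.angle(z1)
    rho2, mu2 = np.abs(z2), np.angle(z2)
    return float((rho2 * np.cos(mu2 - 2.0 * mu1) - rbar**4) / (1.0 - rbar) ** 2)


# ---------------------------------------------------------------------------
# condition-level comparisons


def significance_category(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_conditions(p_first, p_second) -> tuple[str, float]:
    """Paired two-sided Wilcoxon signed-rank on per-run (P_second - P_first).

    Returns (category, p-value) with the category in
    {"n.s.", "*", "**", "***"}. All-zero differences are "n.s." by
    convention. Requires at least 6 runs.
    """
    d = np.asarray(p_second, dtype=float) - np.asarray(p_first, dtype=float)
    if d.size < 6:
        raise ValueError("need at least 6 runs for the paired comparison")
    if np.allclose(d, 0.0):
        return "n.s.", 1.0
    res = stats.wilcoxon(d, alternative="two-sided")
    return significance_category(res.pvalue), float(res.pvalue)


def first_zero_crossing(t, y, zero_eps: float = 0.0) -> float:
    """Linearly interpolated first sign change of y(t); NaN if none.

    Samples with |y| <= zero_eps count as exact zeros: when a statistic
    saturates (e.g. both items recalled perfectly around the transition),
    the difference curve carries a plateau of numerical dust, and the
    crossing is the first time the curve reaches the plateau from below.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need matching t/y samples, at least 2")
    s = np.where(np.abs(y) <= zero_eps, 0.0, np.sign(y))
    started_negative = False
    for k in range(len(y)):
        if s[k] < 0:
            started_negative = True
        if started_negative and s[k] == 0:
            return float(t[k])
        if k + 1 < len(y) and s[k] * s[k + 1] < 0:
            f = y[k] / (y[k] - y[k + 1])
            return float(t[k] + f * (t[k + 1] - t[k]))
    return float("nan")


def empirical_tc(t_maintain, p_diff, runs=None, n_boot: int = 0,
                 rng: np.random.Generator | None = None,
                 zero_eps: float = 2e-3):
    """Transition moment: zero crossing of mean (P_later - P_earlier).

    ``p_diff`` is the mean difference per maintenance duration; with
    ``runs`` (shape (n_runs, n_t)) and ``n_boot`` > 0 a bootstrap
    percentile CI over runs is also returned as (tc, (lo, hi)).
    NaN indicates no sign change in range. ``zero_eps`` is the resolution
    floor below which a mean difference counts as zero (default: a couple
    of posterior units out of a desk-scale run set).
    """
    t_maintain = np.asarray(t_maintain, dtype=float)
    if t_maintain.size < 3:
        raise ValueError("need the difference curve sampled at >= 3 durations")
    tc = first_zero_crossing(t_maintain, p_diff, zero_eps=zero_eps)
    if runs is None or n_boot <= 0:
        return tc
    runs = np.asarray(runs, dtype=float)
    rng = rng or np.random.default_rng()
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, runs.shape[0], runs.shape[0])
        boots.append(first_zero_crossing(t_maintain, runs[idx].mean(axis=0)))
    boots = np.asarray(boots)
    ok = np.isfinite(boots)
    ci = (
        (float(np.percentile(boots[ok], 2.5)), float(np.percentile(boots[ok], 97.5)))
        if ok.any() else (np.nan, np.nan)
    )
    return tc, ci


def empirical_tc_prime(times, delta_jux) -> float:
    """First zero crossing of the trial-averaged efficacy difference.

    ``times`` are measured from the last item's offset. NaN if the trace
    never changes sign in range.
    """
    return first_zero_crossing(times, delta_jux)


# ---------------------------------------------------------------------------
# synthetic-response fixture


def generate_synthetic_responses(
    true_angles,
    kappa: float,
    weights,
    n_trials: int,
    rng: np.random.Generator,
    target_index: int = 0,
):
    """Sample recall responses from the same mixture family the fit assumes.

    ``true_angles`` lists the item orientations; component order is
    (target, other items in order, uniform) with ``weights`` summing to 1.
    Returns response orientations in [-pi/2, pi/2).
    """
    true_angles = np.asarray(true_angles, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.size != true_angles.size + 1:
        raise ValueError("need one weight per item plus a uniform weight")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    order = [target_index] + [i for i in range(true_angles.size) if i != target_index]
    centers = true_angles[order]
    comp = rng.choice(weights.size, size=n_trials, p=weights)
    out = np.empty(n_trials)
    uniform = comp == weights.size - 1
    out[uniform] = rng.uniform(-np.pi / 2, np.pi / 2, uniform.sum())
    for c in range(centers.size):
        sel = comp == c
        if sel.any():
            dev = rng.vonmises(0.0, kappa, sel.sum()) / 2.0  # un-double
            out[sel] = wrap_orientation(centers[c] + dev)
    return out
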