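"""Experiment orchestration: conditions, parameter sweeps, manifests.

A *run* plays the role of one participant: a batch of trials with fresh
item orientations, integrated in lock-step with one seeded generator. A
*condition* is a set of runs at one maintenance duration; a *transition
experiment* scans maintenance durations bracketing the theoretical
transition and estimates the empirical critical moment T_c (from recall
statistics) alongside T_c'(SIM) (from the simulated efficacy difference)
and the closed-form T_c'(THEO) with matched (u0, x0).

Child seeds are derived deterministically from the root seed and the
(condition, run) labels, so any execution order — or a rerun from a written
manifest — reproduces identical results.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .network import (
    GroupTraceRecorder,
    MeanRateAccumulator,
    NetworkState,
    IntegrationBlowupError,
    make_connectivity,
    run_dynamics,
)
from .params import NetworkParams
from .protocol import StimulusSpec, TaskProtocol, draw_item_angles
from .readout import (
    UndecodableProfileError,
    circular_kurtosis,
    circular_variance,
    compare_conditions,
    decode_population_vector,
    empirical_tc,
    empirical_tc_prime,
    normalized_target_probability,
)
from .ring import wrap_orientation
from .theory import TheoryParams, tc_exact, tc_simplified, tc_three_items

__all__ = [
    "ExperimentPlan",
    "RunStats",
    "ConditionResult",
    "TransitionResult",
    "FIG_T_MAINTAIN_SET",
    "SWEEP_RANGES",
    "bracket_t_maintain",
    "run_condition",
    "run_transition_experiment",
    "run_three_item_experiment",
    "run_sweep",
    "write_manifest",
    "load_manifest",
    "run_from_manifest",
    "write_condition_csvs",
]

log = logging.getLogger("swmsim")

#: maintenance durations used for the full-scale recall-performance curves
FIG_T_MAINTAIN_SET = (0.1, 0.2, 0.3, 0.4, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

#: admissible sweep ranges (seconds) for the STP constants and the gap
SWEEP_RANGES = {"tau_f": (2.0, 8.0), "tau_d": (0.1, 0.4), "t_gap": (0.0, 2.0)}


@dataclass(frozen=True)
class ExperimentPlan:
    """Scale and seeding of an experiment.

    Desk-scale defaults (10 runs x 60 trials, 5 maintenance durations
    bracketing the theoretical transition) keep a full transition
    experiment in the minutes range; :meth:`paper_scale` restores the
    published scale (50 runs x 300 trials for two items, x 500 for three,
    11 maintenance durations).
    """

    m_items: int = 2
    n_runs: int = 10
    n_trials: int = 60
    t_maintain_set: tuple | None = None  # None: bracket the theoretical tc
    seed: int = 0
    group_half_width: float = np.deg2rad(8.0)
    record_stride_s: float = 0.01
    decode_rate_floor: float = 0.0

    def __post_init__(self):
        if self.m_items not in (2, 3):
            raise ValueError("m_items must be 2 or 3")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.n_trials < 20:
            raise ValueError("n_trials must be >= 20")
        if self.n_trials // self.m_items < 20:
            raise ValueError(
                "need >= 20 trials per cued item: "
                f"n_trials={self.n_trials} over {self.m_items} items"
            )

    @classmethod
    def paper_scale(cls, m_items: int = 2, seed: int = 0) -> "ExperimentPlan":
        return cls(
            m_items=m_items,
            n_runs=50,
            n_trials=300 if m_items == 2 else 500,
            t_maintain_set=FIG_T_MAINTAIN_SET,
            seed=seed,
        )

    def replace(self, **changes) -> "ExperimentPlan":
        return dataclasses.replace(self, **changes)


def bracket_t_maintain(tc_theory: float, n_points: int = 5) -> tuple:
    """Maintenance durations bracketing a theoretical transition moment."""
    if not np.isfinite(tc_theory) or tc_theory <= 0:
        raise ValueError("theoretical transition must be positive and finite")
    # the top of the bracket sits ~4.5x the transition: the recency effect
    # peaks there and wanes at longer delays as both traces fade
    factors = np.geomspace(0.25, 4.5, n_points)
    return tuple(float(f * tc_theory) for f in factors)


def _child_seed(root: int, *key: int) -> int:
    ss = np.random.SeedSequence((int(root),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _cond_key(t_maintain: float) -> int:
    return int(round(t_maintain * 1e6))


def _batch_profiles(spec: StimulusSpec, grid, centers: np.ndarray):
    """Per-trial stimulus base profile and support mask, shape (B, N)."""
    diff = wrap_orientation(grid.thetas[None, :] - centers[:, None])
    arg = spec.sharpness * diff
    support = np.abs(arg) <= np.pi / 2
    base = np.where(support, spec.amplitude * np.cos(arg), 0.0)
    return base, support


def _input_fn(base, support, sigma):
    if sigma <= 0.0:
        return lambda t, rng: base
    def fn(t, rng):
        return base + sigma * support * rng.standard_normal(base.shape)
    return fn


@dataclass
class RunStats:
    """Per-run (participant-level) recall statistics."""

    p: np.ndarray          # (M,) normalized target probability per item
    cv: np.ndarray         # (M,) circular variance of recall errors
    ck: np.ndarray         # (M,) circular kurtosis
    kappa: np.ndarray      # (M,) fitted mixture concentration
    n_guess: int           # undecodable trials across the run
    trials: pd.DataFrame   # per-trial rows


@dataclass
class ConditionResult:
    """All runs at one maintenance duration."""

    t_maintain: float
    run_stats: list
    delta_jux: dict                 # (i, j) -> trial/run-averaged trace
    jux_mean: np.ndarray            # (T, M) run-averaged group efficacies
    times: np.ndarray               # maintenance clock (0 = last item offset)
    u0: float                       # matched STP values at stimulus offset
    x0: float
    seeds: tuple

    @property
    def p_runs(self) -> np.ndarray:
        return np.stack([rs.p for rs in self.run_stats])

    @property
    def cv_runs(self) -> np.ndarray:
        return np.stack([rs.cv for rs in self.run_stats])

    @property
    def ck_runs(self) -> np.ndarray:
        return np.stack([rs.ck for rs in self.run_stats])

    def significance(self, i: int = 0, j: int = 1) -> tuple[str, float]:
        """Wilcoxon category for P_j vs P_i (0-based items) across runs."""
        return compare_conditions(self.p_runs[:, i], self.p_runs[:, j])

    def trials_frame(self) -> pd.DataFrame:
        return pd.concat([rs.trials for rs in self.run_stats], ignore_index=True)


def _simulate_run(
    params: NetworkParams,
    protocol: TaskProtocol,
    n_trials: int,
    seed: int,
    half_width: float,
    record_stride_s: float,
    decode_rate_floor: float = 0.0,
):
    """Integrate one run (a batch of trials) and return raw per-trial data.

    Returns (responses, angles, cued, u_off, x_off, group recorder for the
    maintenance window, n_guess_flags). ``responses`` holds NaN for trials
    whose recall profile was undecodable.
    """
    rng = np.random.default_rng(seed)
    m = protocol.n_items
    grid = params.grid()
    conn = make_connectivity(params, grid)

    angles = draw_item_angles(m, rng, size=n_trials,
                              min_separation=grid.spacing)      # (B, M)
    cued = np.tile(np.arange(m), n_trials // m + 1)[:n_trials]
    cued = rng.permutation(cued)                                # balanced 0-based

    # per-trial group membership masks (B, M, N)
    d = np.abs(wrap_orientation(grid.thetas[None, None, :] - angles[..., None]))
    masks = d <= half_width

    stride = max(1, int(round(record_stride_s / params.dt)))
    state = NetworkState.resting(params, batch_shape=(n_trials,))

    enc = protocol.encode_spec
    u_off = np.empty((n_trials, m))
    x_off = np.empty((n_trials, m))
    for i in range(m):
        base, support = _batch_profiles(enc, grid, angles[:, i])
        state = run_dynamics(
            state, _input_fn(base, support, enc.noise_sigma),
            protocol.t_encode, params, conn, rng,
        )
        w = masks[:, i, :].astype(float)
        w /= w.sum(axis=1, keepdims=True)
        u_off[:, i] = np.einsum("bn,bn->b", w, state.u)
        x_off[:, i] = np.einsum("bn,bn->b", w, state.x)
        if i < m - 1:
            state = run_dynamics(state, None, protocol.t_gap, params, conn, rng)

    # maintenance: record group traces on a clock starting at last-item offset
    t_offset = state.t
    maintain_rec = GroupTraceRecorder(masks, params, stride=stride)
    state = run_dynamics(
        state, None, protocol.t_maintain, params, conn, rng, recorders=[maintain_rec]
    )

    # recall: cue centred on each trial's cued item (imprecisely, if the
    # spec carries centre jitter); decode the mean rate profile over the
    # last half of the recall window
    cue_centers = angles[np.arange(n_trials), cued]
    if protocol.recall_spec.center_jitter > 0:
        cue_centers = cue_centers + protocol.recall_spec.center_jitter * \
            rng.standard_normal(n_trials)
    base, support = _batch_profiles(protocol.recall_spec, grid, cue_centers)
    acc = MeanRateAccumulator(
        state.t + protocol.t_recall / 2.0, state.t + protocol.t_recall + params.dt,
        params,
    )
    state = run_dynamics(
        state, _input_fn(base, support, protocol.recall_spec.noise_sigma),
        protocol.t_recall, params, conn, rng, recorders=[acc],
    )

    profiles = acc.profile                                       # (B, N)
    responses = np.full(n_trials, np.nan)
    for b in range(n_trials):
        # optional retrieval-failure readout: profiles that never rise above
        # the floor are guesses (NaN), absorbed by the uniform component
        if decode_rate_floor > 0 and profiles[b].max() < decode_rate_floor:
            continue
        try:
            responses[b] = decode_population_vector(profiles[b], grid)
        except UndecodableProfileError:
            pass  # flagged: stays NaN, treated as a uniform guess downstream
    return responses, angles, cued, u_off, x_off, maintain_rec, t_offset


def _run_statistics(responses, angles, cued, m: int, run_id: int,
                    t_maintain: float) -> RunStats:
    """Mixture fits and circular statistics for one run's trials."""
    p = np.empty(m)
    cv = np.empty(m)
    ck = np.empty(m)
    kappa = np.empty(m)
    rows = []
    n_guess_total = 0
    for i in range(m):
        sel = cued == i
        resp = responses[sel]
        ok = np.isfinite(resp)
        n_guess = int((~ok).sum())
        n_guess_total += n_guess
        target = angles[sel, i]
        err_t = wrap_orientation(resp[ok] - target[ok])
        others = [j for j in range(m) if j != i]
        err_nt = np.stack(
            [wrap_orientation(resp[ok] - angles[sel, j][ok]) for j in others], axis=1
        ) if others else None
        fit = normalized_target_probability(err_t, err_nt, n_guess_trials=n_guess)
        p[i] = fit.p_target
        kappa[i] = fit.kappa
        # dispersion statistics use only decodable trials; with fewer than
        # two the run contributes no CV/CK for this item
        cv[i] = circular_variance(err_t) if err_t.size >= 2 else np.nan
        ck[i] = circular_kurtosis(err_t) if err_t.size >= 2 else np.nan
    idx = np.arange(len(responses))
    target_all = angles[idx, cued]
    rows = pd.DataFrame(
        {
            "run_id": run_id,
            "trial_id": idx,
            "m_items": m,
            "t_maintain": t_maintain,
            "cued_item": cued + 1,
            "theta_true": target_all,
            "theta_recalled": responses,
            "error": wrap_orientation(responses - target_all),
        }
    )
    return RunStats(p=p, cv=cv, ck=ck, kappa=kappa, n_guess=n_guess_total, trials=rows)


def run_condition(
    plan: ExperimentPlan,
    protocol_template: TaskProtocol,
    params: NetworkParams,
    t_maintain: float,
    seeds: tuple | None = None,
) -> ConditionResult:
    """Simulate all runs of one maintenance-duration condition.

    Each run uses ``plan.n_trials`` fresh trials with the cued item balanced
    across items. A run that blows up numerically is retried once with a
    derived fallback seed and logged.
    """
    m = plan.m_items
    protocol = protocol_template.replace(
        t_maintain=float(t_maintain), item_angles=(0.0,) * m
    )
    if seeds is None:
        seeds = tuple(
            _child_seed(plan.seed, _cond_key(t_maintain), r) for r in range(plan.n_runs)
        )
    run_stats = []
    jux_sum = 0.0
    u0_acc, x0_acc = [], []
    times = None
    for run_id, seed in enumerate(seeds):
        try:
            out = _simulate_run(
                params, protocol, plan.n_trials, seed,
                plan.group_half_width, plan.record_stride_s,
                plan.decode_rate_floor,
            )
        except IntegrationBlowupError as err:  # pragma: no cover - defensive
            log.warning("run %d failed (%s); resampling once", run_id, err)
            out = _simulate_run(
                params, protocol, plan.n_trials, _child_seed(seed, 999),
                plan.group_half_width, plan.record_stride_s,
                plan.decode_rate_floor,
            )
        responses, angles, cued, u_off, x_off, rec, t_offset = out
        run_stats.append(
            _run_statistics(responses, angles, cued, m, run_id, t_maintain)
        )
        jux_sum = jux_sum + rec.group_jux.mean(axis=1)  # average over trials -> (T, M)
        u0_acc.append(u_off.mean())
        x0_acc.append(x_off.mean())
        if times is None:
            times = rec.times - t_offset
        log.info("t_maintain=%.3gs run %d/%d done", t_maintain, run_id + 1, len(seeds))

    jux_mean = jux_sum / len(seeds)
    delta = {
        (i, j): jux_mean[:, j] - jux_mean[:, i]
        for i in range(m) for j in range(i + 1, m)
    }
    return ConditionResult(
        t_maintain=float(t_maintain),
        run_stats=run_stats,
        delta_jux=delta,
        jux_mean=jux_mean,
        times=times,
        u0=float(np.mean(u0_acc)),
        x0=float(np.mean(x0_acc)),
        seeds=tuple(seeds),
    )


@dataclass
class TransitionResult:
    """A transition experiment: conditions over maintenance durations."""

    conditions: list
    t_maintain_set: tuple
    tc_empirical: dict      # statistic name -> interpolated crossing (s)
    tc_prime_sim: float     # zero crossing of the simulated efficacy difference
    tc_prime_theo: float    # closed form with matched (u0, x0)
    tc_prime_theo_biased: float  # simplified form including the cue bias t_b
    theory: TheoryParams
    pair: tuple = (0, 1)

    def p_diff(self, i=None, j=None) -> np.ndarray:
        i, j = (self.pair if i is None else (i, j))
        return np.array(
            [c.p_runs[:, j].mean() - c.p_runs[:, i].mean() for c in self.conditions]
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            m = c.p_runs.shape[1]
            try:
                pair_sig = c.significance(*self.pair)[0]
            except ValueError:
                pair_sig = "n/a"  # too few runs for the paired test
            for i in range(m):
                sig = pair_sig
                rows.append(
                    {
                        "t_maintain": c.t_maintain,
                        "item": i + 1,
                        "P": c.p_runs[:, i].mean(),
                        "CV": c.cv_runs[:, i].mean(),
                        "CK": c.ck_runs[:, i].mean(),
                        "n_runs": c.p_runs.shape[0],
                        "significance": sig,
                    }
                )
        return pd.DataFrame(rows)


def _transition_from_conditions(conditions, t_set, protocol, params, pair):
    i, j = pair
    p_diff = np.array(
        [c.p_runs[:, j].mean() - c.p_runs[:, i].mean() for c in conditions]
    )
    cv_diff = np.array(
        [c.cv_runs[:, i].mean() - c.cv_runs[:, j].mean() for c in conditions]
    )
    ck_diff = np.array(
        [c.ck_runs[:, j].mean() - c.ck_runs[:, i].mean() for c in conditions]
    )
    t_set_arr = np.asarray(t_set)
    tc_emp = {
        "P": empirical_tc(t_set_arr, p_diff),
        "CV": empirical_tc(t_set_arr, cv_diff),
        "CK": empirical_tc(t_set_arr, ck_diff),
    }
    longest = conditions[int(np.argmax(t_set_arr))]
    tc_sim = empirical_tc_prime(longest.times, longest.delta_jux[pair])
    u0 = float(np.mean([c.u0 for c in conditions]))
    x0 = float(np.mean([c.x0 for c in conditions]))
    theo = TheoryParams(
        u0=u0, x0=x0, tau_f=params.tau_f, tau_d=params.tau_d,
        t_star=protocol.t_star, t_b=params.tau, j_peak=params.j_peak,
    )
    return TransitionResult(
        conditions=list(conditions),
        t_maintain_set=tuple(t_set),
        tc_empirical=tc_emp,
        tc_prime_sim=float(tc_sim),
        tc_prime_theo=float(tc_exact(theo)),
        tc_prime_theo_biased=float(tc_simplified(theo)),
        theory=theo,
        pair=pair,
    )


def _default_t_set(plan, protocol, params, nominal_u0=0.75, nominal_x0=0.2):
    theo = TheoryParams(
        u0=nominal_u0, x0=nominal_x0, tau_f=params.tau_f, tau_d=params.tau_d,
        t_star=protocol.t_star,
    )
    return bracket_t_maintain(tc_exact(theo))


def run_transition_experiment(
    plan: ExperimentPlan,
    protocol_template: TaskProtocol,
    params: NetworkParams,
    pair: tuple = (0, 1),
) -> TransitionResult:
    """Scan maintenance durations and locate the primacy-recency transition."""
    t_set = plan.t_maintain_set or _default_t_set(plan, protocol_template, params)
    conditions = [
        run_condition(plan, protocol_template, params, tm) for tm in t_set
    ]
    return _transition_from_conditions(
        conditions, t_set, protocol_template, params, pair
    )


def _default_t_set_three(protocol, params, nominal_x0=0.1):
    """Maintenance grid bracketing both pairwise transitions of a 3-item task.

    The 1-2 transition sits one stride t* before the 2-3 transition (exact
    consequence of the shift relation between group traces), so it is
    observable only when t* is short enough that tc > t*; otherwise the
    first item's advantage is already gone when maintenance starts.
    """
    theo = TheoryParams(
        u0=0.9, x0=nominal_x0, tau_f=params.tau_f, tau_d=params.tau_d,
        t_star=protocol.t_star,
    )
    t23 = tc_exact(theo) + params.tau
    t12 = t23 - protocol.t_star
    if not np.isfinite(t12) or t12 <= 0:
        raise ValueError(
            "the 1-2 transition precedes maintenance onset for this stride "
            f"(t*={protocol.t_star:.3g}s); shorten t_gap/t_encode to observe it"
        )
    return tuple(sorted(
        {0.4 * t12, 0.85 * t12, 1.3 * t12, 0.85 * t23, 1.4 * t23,
         2.4 * t23, 3.4 * t23}
    ))


def run_three_item_experiment(
    plan: ExperimentPlan,
    protocol_template: TaskProtocol,
    params: NetworkParams,
):
    """Three-item transition: returns (result_12, result_23) sharing conditions.

    Checks and reports both pairwise critical moments; the 1-2 transition
    precedes the 2-3 transition by about one inter-item stride.
    """
    if plan.m_items != 3:
        raise ValueError("plan.m_items must be 3")
    t_set = plan.t_maintain_set or _default_t_set_three(protocol_template, params)
    conditions = [run_condition(plan, protocol_template, params, tm) for tm in t_set]
    res12 = _transition_from_conditions(
        conditions, t_set, protocol_template, params, (0, 1)
    )
    res23 = _transition_from_conditions(
        conditions, t_set, protocol_template, params, (1, 2)
    )
    return res12, res23


# ---------------------------------------------------------------------------
# parameter sweeps


def run_sweep(
    plan: ExperimentPlan,
    protocol_template: TaskProtocol,
    params: NetworkParams,
    axes: dict,
) -> pd.DataFrame:
    """Grid sweep over up to two of tau_f / tau_d / t_gap.

    ``axes`` maps axis names to value arrays; every grid point runs a full
    (desk-scale) transition experiment. Returns a table with one row per
    grid point carrying the empirical T_c under all three statistics,
    T_c'(SIM) and the closed forms; missing crossings are NaN.
    """
    for name, values in axes.items():
        if name not in SWEEP_RANGES:
            raise ValueError(f"unknown sweep axis {name!r}")
        lo, hi = SWEEP_RANGES[name]
        v = np.asarray(values, dtype=float)
        if v.min() < lo or v.max() > hi:
            raise ValueError(f"{name} values outside the admissible range [{lo}, {hi}]")
    names = list(axes)
    mesh = np.meshgrid(*[np.asarray(axes[n], dtype=float) for n in names],
                       indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)

    rows = []
    for values in points:
        p = params
        proto = protocol_template
        for name, val in zip(names, values):
            if name == "t_gap":
                proto = proto.replace(t_gap=float(val))
            else:
                p = p.replace(**{name: float(val)})
        res = run_transition_experiment(plan, proto, p)
        row = {name: float(val) for name, val in zip(names, values)}
        row.update(
            {
                "t_star": proto.t_star,
                "u0": res.theory.u0,
                "x0": res.theory.x0,
                "tc_P": res.tc_empirical["P"],
                "tc_CV": res.tc_empirical["CV"],
                "tc_CK": res.tc_empirical["CK"],
                "tc_prime_sim": res.tc_prime_sim,
                "tc_exact": res.tc_prime_theo,
                "tc_simplified": res.tc_prime_theo_biased,
            }
        )
        rows.append(row)
        log.info("sweep point %s done", row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# manifests and CSV output


_CSV_FLOAT = "%.6g"


def write_manifest(
    plan: ExperimentPlan,
    params: NetworkParams,
    protocol: TaskProtocol,
    t_maintain_set,
    out_dir: str | Path,
) -> Path:
    """Write a JSON manifest sufficient to re-run the experiment bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child = {
        f"{_cond_key(tm)}": [
            _child_seed(plan.seed, _cond_key(tm), r) for r in range(plan.n_runs)
        ]
        for tm in t_maintain_set
    }
    manifest = {
        "package_version": _pkg_version,
        "root_seed": int(plan.seed),
        "child_seeds": child,
        "plan": dataclasses.asdict(plan),
        "t_maintain_set": [float(t) for t in t_maintain_set],
        "params": params.to_config(),
        "protocol": {
            "t_encode": protocol.t_encode,
            "t_gap": protocol.t_gap,
            "t_recall": protocol.t_recall,
            "encode": {
                "amplitude": protocol.encode_spec.amplitude,
                "sharpness": protocol.encode_spec.sharpness,
                "noise_sigma": protocol.encode_spec.noise_sigma,
                "center_jitter": float(protocol.encode_spec.center_jitter),
            },
            "recall": {
                "amplitude": protocol.recall_spec.amplitude,
                "sharpness": protocol.recall_spec.sharpness,
                "noise_sigma": protocol.recall_spec.noise_sigma,
                "center_jitter": float(protocol.recall_spec.center_jitter),
            },
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_manifest(path: str | Path) -> dict:
    manifest = json.loads(Path(path).read_text())
    for key in ("root_seed", "plan", "params", "protocol", "t_maintain_set"):
        if key not in manifest:
            raise ValueError(f"manifest missing required key {key!r}")
    return manifest


def _objects_from_manifest(manifest: dict):
    plan_dict = dict(manifest["plan"])
    t_set = plan_dict.pop("t_maintain_set", None)
    plan = ExperimentPlan(**{**plan_dict, "t_maintain_set":
                             tuple(t_set) if t_set else None})
    params = NetworkParams.from_config(manifest["params"])
    proto_cfg = manifest["protocol"]
    protocol = TaskProtocol(
        item_angles=(0.0,),  # placeholder; per-trial angles are drawn in-run
        t_encode=proto_cfg["t_encode"],
        t_gap=proto_cfg["t_gap"],
        t_recall=proto_cfg["t_recall"],
        encode_spec=StimulusSpec(**proto_cfg["encode"]),
        recall_spec=StimulusSpec(**proto_cfg["recall"]),
    )
    return plan, params, protocol, tuple(manifest["t_maintain_set"])


def write_condition_csvs(result: TransitionResult, out_dir: str | Path) -> list:
    """Write per-trial and per-condition CSVs (6 significant digits)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = pd.concat([c.trials_frame() for c in result.conditions],
                       ignore_index=True)
    cond = result.summary_frame()
    paths = [out_dir / "trials.csv", out_dir / "conditions.csv"]
    trials.to_csv(paths[0], index=False, float_format=_CSV_FLOAT)
    cond.to_csv(paths[1], index=False, float_format=_CSV_FLOAT)
    summary = {
        "tc_empirical": {k: v for k, v in result.tc_empirical.items()},
        "tc_prime_sim": result.tc_prime_sim,
        "tc_prime_theo": result.tc_prime_theo,
        "u0": result.theory.u0,
        "x0": result.theory.x0,
    }
    spath = out_dir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths.append(spath)
    return paths


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path):
    """Re-run a transition experiment from its manifest and rewrite CSVs.

    Given the same package version this reproduces byte-identical outputs.
    """
    manifest = load_manifest(manifest_path)
    plan, params, protocol, t_set = _objects_from_manifest(manifest)
    plan = plan.replace(t_maintain_set=t_set)
    result = run_transition_experiment(plan, protocol, params)
    write_manifest(plan, params, protocol, t_set, out_dir)
    return result, write_condition_csvs(result, out_dir)
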