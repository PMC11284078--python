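"""Delay-recall task: stimulus profiles and per-trial time courses.

A trial presents M orientation stimuli in sequence (each for t_encode,
separated by t_gap), waits t_maintain after the last item's offset, then
presents a weak recall cue for t_recall. The cue is centred on the cued
item's true orientation but is much weaker and spatially broader than the
encoding stimuli, so retrieval is driven by the facilitated synapses rather
than by the cue itself.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .ring import RingGrid, wrap_orientation

__all__ = [
    "StimulusSpec",
    "TaskProtocol",
    "Interval",
    "TWO_ITEM_DELTAS",
    "THREE_ITEM_DELTAS",
    "stimulus_profile",
    "draw_item_angles",
    "build_schedule",
    "two_item_protocol",
    "three_item_protocol",
    "load_protocol",
    "save_protocol",
]

# Orientation differences between successive items, drawn per trial
# (degrees, both signs), for the two- and three-item task variants.
_TWO_DEG = (17.0, 24.0, 38.0, 52.0, 66.0, 80.0)
_THREE_DEG = (12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0)
TWO_ITEM_DELTAS = tuple(np.deg2rad(d) * s for d in _TWO_DEG for s in (1, -1))
THREE_ITEM_DELTAS = tuple(np.deg2rad(d) * s for d in _THREE_DEG for s in (1, -1))


@dataclass(frozen=True)
class StimulusSpec:
    """Spatial profile of an external signal on the orientation ring.

    The drive is amplitude*cos[sharpness*(theta-center)] wherever
    |sharpness*(theta-center)| <= pi/2 (wrapped difference) and zero
    outside; ``noise_sigma`` adds white noise inside the support, redrawn
    every integration step. ``center_jitter`` is the standard deviation
    (radians) of a per-trial error on the centre: an imprecise signal
    points near, not at, its nominal orientation. Retrieval corrects the
    error only when the cue manages to reignite the memory trace.
    """

    amplitude: float
    sharpness: float
    center: float = 0.0
    noise_sigma: float = 0.0
    center_jitter: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be > 0")
        if self.center_jitter < 0:
            raise ValueError("center_jitter must be >= 0")

    def at(self, center: float) -> "StimulusSpec":
        return replace(self, center=float(center))


def stimulus_profile(
    spec: StimulusSpec, grid: RingGrid, rng: np.random.Generator | None = None
):
    """Evaluate a stimulus over the ring; optionally with one noise draw.

    ``spec.center`` may be a scalar or an array of per-trial centres, in
    which case the result has a matching leading batch axis.
    """
    center = np.atleast_1d(np.asarray(spec.center, dtype=float))
    diff = wrap_orientation(grid.thetas[None, :] - center[..., None])
    arg = spec.sharpness * diff
    support = np.abs(arg) <= np.pi / 2
    base = np.where(support, spec.amplitude * np.cos(arg), 0.0)
    if rng is not None and spec.noise_sigma > 0.0:
        base = base + spec.noise_sigma * support * rng.standard_normal(base.shape)
    if np.isscalar(spec.center) or np.ndim(spec.center) == 0:
        return base[0]
    return base


def draw_item_angles(
    m: int,
    rng: np.random.Generator,
    delta_set=None,
    min_separation: float = np.pi / 180,
    size: int | None = None,
) -> np.ndarray:
    """Draw the item orientations for one trial (or a batch of trials).

    The first orientation is uniform on [-pi/2, pi/2); each later item sits
    at theta_1 + delta with delta drawn independently from ``delta_set``
    (defaults: the two-item set for m=2, the three-item set for m=3).
    Configurations whose wrapped orientations collide within
    ``min_separation`` are redrawn.

    Returns shape (m,) or (size, m).
    """
    if m not in (2, 3) and delta_set is None:
        raise ValueError("default delta sets exist only for m in {2, 3}")
    if delta_set is None:
        delta_set = TWO_ITEM_DELTAS if m == 2 else THREE_ITEM_DELTAS
    delta_set = np.asarray(delta_set, dtype=float)
    if delta_set.size == 0:
        raise ValueError("delta_set must be non-empty")

    n = 1 if size is None else int(size)
    out = np.empty((n, m))
    for i in range(n):
        while True:
            theta1 = rng.uniform(-np.pi / 2, np.pi / 2)
            deltas = rng.choice(delta_set, size=m - 1)
            angles = wrap_orientation(np.concatenate(([theta1], theta1 + deltas)))
            d = np.abs(wrap_orientation(angles[:, None] - angles[None, :]))
            if np.all(d[np.triu_indices(m, 1)] >= min_separation):
                out[i] = angles
                break
    return out[0] if size is None else out


@dataclass(frozen=True)
class TaskProtocol:
    """One delay-recall trial: item orientations, timings and signal specs.

    ``cued_item`` is 1-based (item 1 is presented first). The maintenance
    clock starts at the offset of the last item; there is no gap after the
    final item, so the inter-item stride is t* = t_encode + t_gap.
    """

    item_angles: tuple
    t_encode: float = 0.25
    t_gap: float = 1.0
    t_maintain: float = 2.0
    t_recall: float = 0.2
    encode_spec: StimulusSpec = StimulusSpec(
        amplitude=20.0, sharpness=6.0, noise_sigma=1.0)
    recall_spec: StimulusSpec = StimulusSpec(
        amplitude=2.0, sharpness=1.0, noise_sigma=4.0,
        center_jitter=np.deg2rad(12.0))
    cued_item: int = 1

    def __post_init__(self):
        angles = tuple(float(a) for a in np.atleast_1d(self.item_angles))
        object.__setattr__(self, "item_angles", angles)
        if len(angles) < 1:
            raise ValueError("need at least one item")
        for name in ("t_encode", "t_gap", "t_maintain", "t_recall"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1 <= self.cued_item <= len(angles)):
            raise ValueError("cued_item out of range")
        if not self.encode_spec.amplitude > self.recall_spec.amplitude:
            raise ValueError("encoding must be much stronger than the recall cue")
        if not self.encode_spec.sharpness > self.recall_spec.sharpness:
            raise ValueError("encoding must be sharper than the recall cue")

    @property
    def n_items(self) -> int:
        return len(self.item_angles)

    @property
    def t_star(self) -> float:
        """Inter-item stride t* = t_encode + t_gap."""
        return self.t_encode + self.t_gap

    @property
    def total_duration(self) -> float:
        m = self.n_items
        return m * self.t_encode + (m - 1) * self.t_gap + self.t_maintain + self.t_recall

    def replace(self, **changes) -> "TaskProtocol":
        return replace(self, **changes)


@dataclass(frozen=True)
class Interval:
    """One schedule segment: a duration and the active stimulus (or None)."""

    label: str
    duration: float
    spec: StimulusSpec | None


def two_item_protocol(**overrides) -> TaskProtocol:
    """The default two-item delay-recall design (stride t* = 1.25 s)."""
    return TaskProtocol(item_angles=(0.0, 0.0)).replace(**overrides)


def three_item_protocol(**overrides) -> TaskProtocol:
    """The default three-item design: a short stride (t* = 0.4 s).

    With three items the earlier pairwise transition happens one stride
    before the later one; a short inter-item gap keeps both transitions
    inside the maintenance period where they can be measured.
    """
    return TaskProtocol(item_angles=(0.0, 0.0, 0.0), t_gap=0.15).replace(**overrides)


def build_schedule(protocol: TaskProtocol) -> list[Interval]:
    """Expand a protocol into ordered (interval, active stimulus) segments.

    encode_1, gap_1, ..., encode_M, maintain, recall — no gap after the
    last item, so maintenance starts at the last item's offset.
    """
    p = protocol
    out: list[Interval] = []
    for i, theta in enumerate(p.item_angles, start=1):
        out.append(Interval(f"encode_{i}", p.t_encode, p.encode_spec.at(theta)))
        if i < p.n_items:
            out.append(Interval(f"gap_{i}", p.t_gap, None))
    out.append(Interval("maintain", p.t_maintain, None))
    cue_center = p.item_angles[p.cued_item - 1]
    out.append(Interval("recall", p.t_recall, p.recall_spec.at(cue_center)))
    return out


# --- config serialization ---------------------------------------------------


def _spec_to_dict(s: StimulusSpec) -> dict:
    return {
        "amplitude": float(s.amplitude),
        "sharpness": float(s.sharpness),
        "center": float(s.center),
        "noise_sigma": float(s.noise_sigma),
        "center_jitter": float(s.center_jitter),
    }


def save_protocol(protocol: TaskProtocol, path: str | Path) -> None:
    cfg = {
        "items": {"angles": list(protocol.item_angles), "cued_item": protocol.cued_item},
        "timing": {
            "t_encode": protocol.t_encode,
            "t_gap": protocol.t_gap,
            "t_maintain": protocol.t_maintain,
            "t_recall": protocol.t_recall,
        },
        "encode": _spec_to_dict(protocol.encode_spec),
        "recall": _spec_to_dict(protocol.recall_spec),
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_protocol(path: str | Path) -> TaskProtocol:
    cfg = yaml.safe_load(Path(path).read_text())
    return TaskProtocol(
        item_angles=tuple(cfg["items"]["angles"]),
        cued_item=cfg["items"]["cued_item"],
        encode_spec=StimulusSpec(**cfg["encode"]),
        recall_spec=StimulusSpec(**cfg["recall"]),
        **cfg["timing"],
    )
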