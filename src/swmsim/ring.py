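"""Ring geometry for an orientation-coding network.

Preferred orientations are pi-periodic and live on [-pi/2, pi/2). All angle
differences on the ring are wrapped into that interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RingGrid", "wrap_orientation"]

HALF_PI = np.pi / 2.0


def wrap_orientation(angle):
    """Wrap an orientation (or difference of orientations) into [-pi/2, pi/2).

    Orientation is pi-periodic, so differences larger than a quarter turn
    wrap around to the opposite sign.
    """
    return (np.asarray(angle) + HALF_PI) % np.pi - HALF_PI


@dataclass(frozen=True)
class RingGrid:
    """N preferred orientations uniformly tiling [-pi/2, pi/2).

    The spacing is pi/N; neuron k sits at -pi/2 + k*pi/N.
    """

    n: int
    thetas: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.n < 8:
            raise ValueError(f"need at least 8 ring positions, got {self.n}")
        thetas = -HALF_PI + np.arange(self.n) * (np.pi / self.n)
        thetas.setflags(write=False)
        object.__setattr__(self, "thetas", thetas)

    @property
    def spacing(self) -> float:
        return np.pi / self.n

    def wrapped_diff(self, a, b):
        """Pairwise-safe wrapped difference a - b on the orientation ring."""
        return wrap_orientation(np.asarray(a) - np.asarray(b))
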