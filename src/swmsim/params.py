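"""Static network, plasticity and integration constants, with config file I/O.

Units are seconds and radians throughout. The defaults describe a
facilitation-dominant prefrontal-like regime: the facilitation time constant
tau_f (seconds) far exceeds the depression recovery constant tau_d, and the
baseline release probability increment U0 is modest, so a transient burst of
firing leaves behind an elevated release probability u that outlives the
depleted vesicle pool x. Connectivity constants (j_peak, j_floor, j_ei, j_ie)
are calibrated so that an encoding stimulus evokes a transient bump, the
network falls silent after stimulus offset, and a weak recall cue re-ignites
activity preferentially at the most facilitated location; see
:func:`swmsim.network.check_operating_regime`.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .ring import RingGrid

__all__ = ["NetworkParams", "load_params", "save_params"]


@dataclass(frozen=True)
class NetworkParams:
    """All static constants of the ring network with short-term plasticity.

    Parameters
    ----------
    n_neurons
        Number of excitatory neurons N tiling the orientation ring.
    tau
        Membrane/synaptic time constant (s), shared by the excitatory ring
        and the inhibitory pool.
    rho
        Neuronal density (neurons per radian). ``None`` means N/pi, which
        makes the discretized recurrent integral a plain sum over neurons.
    j_peak, j_floor
        Peak (J) and floor (J0) of the translation-invariant cosine
        connectivity. The floor is negative: weak surround suppression.
    b_width
        Dimensionless sharpness B of the connectivity cosine; the cosine
        applies while |B*(theta-theta')| <= arccos(-J0/J), the floor beyond.
    j_ei, j_ie
        Coupling from the global inhibitory pool to the ring and back.
    alpha
        Gain of the smoothed threshold-linear rate function
        r = alpha*log(1+exp(h/alpha)).
    i0
        Constant background drive; subthreshold (negative) so the silent
        state is stable.
    sigma0
        Background noise strength; white noise of this amplitude enters the
        excitatory drive each step.
    tau_f, tau_d
        Facilitation and depression time constants (s); tau_f > tau_d.
    u_increment
        U0, the per-spike increment factor of the release probability.
    dt
        Euler-Maruyama step (s); must satisfy dt <= tau/10.
    """

    n_neurons: int = 180
    tau: float = 0.01
    rho: float | None = None
    j_peak: float = 1.2
    j_floor: float = -0.12
    b_width: float = 5.0
    j_ei: float = 2.0
    j_ie: float = 2.0
    alpha: float = 1.5
    i0: float = -5.0
    sigma0: float = 0.1
    tau_f: float = 4.0
    tau_d: float = 0.3
    u_increment: float = 0.3
    dt: float = 5e-4

    def __post_init__(self):
        if self.n_neurons < 8:
            raise ValueError("n_neurons must be >= 8")
        if self.dt <= 0 or self.tau <= 0:
            raise ValueError("dt and tau must be positive")
        if not (self.tau_f > self.tau_d > 0):
            raise ValueError(
                "facilitation-dominant regime requires tau_f > tau_d > 0 "
                f"(got tau_f={self.tau_f}, tau_d={self.tau_d})"
            )
        if not (0.0 < self.u_increment <= 1.0):
            raise ValueError("u_increment must lie in (0, 1]")
        if self.j_peak == 0 or abs(self.j_floor / self.j_peak) > 1.0:
            raise ValueError(
                "arccos(-j_floor/j_peak) undefined: need |j_floor/j_peak| <= 1 "
                f"(got j_floor={self.j_floor}, j_peak={self.j_peak})"
            )
        if self.dt > self.tau / 10.0:
            raise ValueError(
                f"dt={self.dt} too coarse for tau={self.tau}: require dt <= tau/10"
            )
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.rho is None:
            object.__setattr__(self, "rho", self.n_neurons / np.pi)

    def grid(self) -> RingGrid:
        return RingGrid(self.n_neurons)

    def replace(self, **changes) -> "NetworkParams":
        return dataclasses.replace(self, **changes)

    # --- config file round trip (flat namespacing: network.* / stp.* / integration.*)

    _NETWORK_KEYS = (
        "n_neurons", "tau", "rho", "j_peak", "j_floor", "b_width",
        "j_ei", "j_ie", "alpha", "i0", "sigma0",
    )
    _STP_KEYS = ("tau_f", "tau_d", "u_increment")

    def to_config(self) -> dict:
        return {
            "network": {k: getattr(self, k) for k in self._NETWORK_KEYS},
            "stp": {k: getattr(self, k) for k in self._STP_KEYS},
            "integration": {"dt": self.dt},
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "NetworkParams":
        kwargs = {}
        kwargs.update(cfg.get("network", {}))
        kwargs.update(cfg.get("stp", {}))
        kwargs.update(cfg.get("integration", {}))
        return cls(**kwargs)


def save_params(params: NetworkParams, path: str | Path) -> None:
    """Write parameters to a YAML config with network/stp/integration sections."""
    Path(path).write_text(yaml.safe_dump(params.to_config(), sort_keys=True))


def load_params(path: str | Path) -> NetworkParams:
    """Read parameters from a YAML config written by :func:`save_params`."""
    cfg = yaml.safe_load(Path(path).read_text())
    return NetworkParams.from_config(cfg)
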