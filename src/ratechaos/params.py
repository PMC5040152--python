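"""Model parameter container and config-file handling.

All times are in milliseconds and all voltages in millivolts throughout the
package; firing rates cross module boundaries in Hz (spikes/s) but are held
internally in spikes/ms where noted.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ModelParams", "QIFParams", "load_defaults", "default_params", "scale_network"]


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Parameters of the sparse balanced E/I network of LIF neurons.

    The network has ``N`` neurons, a fraction ``f_E`` of them excitatory, and
    every neuron receives exactly ``C`` synapses: ``C_E = round(f_E*C)`` from
    excitatory and ``C_I = C - C_E`` from inhibitory neurons, with weights
    ``+J`` and ``-g*J`` (mV jumps of the membrane potential).
    """

    N: int = 10000
    C: int = 1000
    f_E: float = 0.8
    J: float = 0.5
    g: float = 5.0
    delta: float = 0.55
    tau_m: float = 20.0
    theta: float = 20.0
    V_r: float = 10.0
    tau_rp: float = 0.5
    mu0: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not (0 <= self.C < self.N):
            raise ValueError("need 0 <= C < N")
        if not (0.0 < self.f_E < 1.0):
            raise ValueError("f_E must lie in (0, 1)")
        if self.J < 0 or self.g < 0:
            raise ValueError("J and g must be non-negative")
        if self.delta < 0 or self.tau_rp < 0:
            raise ValueError("delta and tau_rp must be non-negative")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.theta <= self.V_r:
            raise ValueError("theta must exceed V_r")

    @property
    def N_E(self) -> int:
        return int(round(self.f_E * self.N))

    @property
    def N_I(self) -> int:
        return self.N - self.N_E

    @property
    def C_E(self) -> int:
        return int(round(self.f_E * self.C))

    @property
    def C_I(self) -> int:
        return self.C - self.C_E

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass(frozen=True)
class QIFParams:
    """Quadratic integrate-and-fire variant, matched to the LIF.

    Subthreshold flow ``tau_m dV/dt = (V - V_q)^2/dV_q + mu - theta``; the
    rheobase is ``mu = theta`` for any curvature, matching the LIF.  A spike
    is emitted at ``V_peak`` and the voltage resets to ``V_reset``.

    ``dV_q`` sets the width of the slowly-moving region around ``V_q``
    (at subthreshold drive mu the unstable fixed point sits
    sqrt((theta-mu) dV_q) above V_q).  It is chosen much larger than the
    LIF's theta - V_r so that the very strong synaptic jumps used in the
    strong-coupling control (J = 20 mV) stay small relative to the
    subthreshold operating range, as they are for the LIF at its
    couplings; V_peak and V_reset lie well outside that range.
    """

    V_q: float = 15.0
    dV_q: float = 400.0
    V_peak: float = 300.0
    V_reset: float = -270.0


def load_defaults() -> dict:
    """Load the versioned default configuration shipped with the package."""
    text = resources.files("ratechaos").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_params(config: str | Path | None = None, **overrides) -> ModelParams:
    """Build a :class:`ModelParams` from the default (or a user) config file."""
    if config is None:
        cfg = load_defaults()
    else:
        cfg = yaml.safe_load(Path(config).read_text())
    fields = dict(cfg["model"])
    fields.update(overrides)
    return ModelParams(**fields)


def scale_network(params: ModelParams, factor: float) -> ModelParams:
    """Rescale the network size keeping the connection probability C/N constant.

    ``factor`` must map both N and C to integers; e.g. factor=4 takes the
    (N=10000, C=1000) network to (N=40000, C=4000).
    """
    N = params.N * factor
    C = params.C * factor
    if abs(N - round(N)) > 1e-9 or abs(C - round(C)) > 1e-9:
        raise ValueError(f"factor {factor} does not yield integral N and C")
    return params.replace(N=int(round(N)), C=int(round(C)))
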