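"""Parameter containers for the three-population neural mass model.

The model lumps a cortical micro-circuit into a pyramidal-cell population,
somatostatin-positive (SOM+, slow dendrite-projecting) interneurons and
parvalbumin-positive (PV+, fast soma-projecting) interneurons.  Each
population converts its mean membrane potential into a firing rate through
a sigmoid "pulse-to-wave" function and converts incoming firing rates into
post-synaptic potentials (PSPs) through a second-order linear filter with
gain ``W`` and time constant ``tau``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SigmoidParams",
    "ModelParams",
    "TimescaleParams",
    "StimCoupling",
    "sigmoid",
    "sigmoid_deriv",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Firing-rate sigmoid S(v) = vmax / (1 + exp(steepness * (threshold - v))).

    Parameters
    ----------
    vmax : float
        Firing-rate ceiling in s^-1.
    steepness : float
        Slope parameter in mV^-1.
    threshold : float
        Half-activation potential in mV; S(threshold) = vmax / 2.
    """

    vmax: float = 5.0
    steepness: float = 0.56
    threshold: float = 6.0

    def __post_init__(self) -> None:
        if not (self.vmax > 0):
            raise ValueError("vmax must be positive")
        if not (self.steepness > 0):
            raise ValueError("steepness must be positive")


_DEFAULT_SIGMOID = SigmoidParams()


def sigmoid(v, params: SigmoidParams = _DEFAULT_SIGMOID):
    """Population firing rate (s^-1) for mean membrane potential ``v`` (mV).

    Strictly increasing, bounded in (0, vmax).  Accepts scalars or arrays;
    raises on non-finite scalar input.
    """
    if np.isscalar(v):
        if not math.isfinite(v):
            raise ValueError("sigmoid: non-finite membrane potential")
        z = params.steepness * (params.threshold - v)
        # guard exp overflow far in the hyperpolarized tail
        if z > 700.0:
            return params.vmax * math.exp(-z)
        return params.vmax / (1.0 + math.exp(z))
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid: non-finite membrane potential")
    z = np.clip(params.steepness * (params.threshold - v), -700.0, 700.0)
    return params.vmax / (1.0 + np.exp(z))


def sigmoid_deriv(v, params: SigmoidParams = _DEFAULT_SIGMOID):
    """dS/dv, closed form: steepness * S * (1 - S / vmax)."""
    s = sigmoid(v, params)
    return params.steepness * s * (1.0 - s / params.vmax)


@dataclass(frozen=True)
class ModelParams:
    """Synaptic gains, time constants, connectivities and input statistics.

    Defaults are the background-activity operating point: A (glutamatergic
    gain, mV), B (SOM+ GABAergic gain, mV), G (PV+ GABAergic gain, mV),
    tau_a/tau_b/tau_g (synaptic time constants, s), p_mean (mean external
    cortical input, Hz), sigma (input noise standard deviation, Hz) and the
    average synaptic contact numbers C1..C7 (dimensionless).
    """

    A: float = 5.0
    B: float = 40.0
    G: float = 35.0
    tau_a: float = 0.01
    tau_b: float = 0.05
    tau_g: float = 0.003
    p_mean: float = 90.0
    sigma: float = 0.0
    C1: float = 135.0
    C2: float = 108.0
    C3: float = 35.0
    C4: float = 25.0
    C5: float = 450.0
    C6: float = 121.0
    C7: float = 121.0
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        for name in ("tau_a", "tau_b", "tau_g"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in ("A", "B", "G", "C1", "C2", "C3", "C4", "C5", "C6", "C7"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def delta(self) -> float:
        """Timescale ratio tau_g / tau_a (0.3 at defaults)."""
        return self.tau_g / self.tau_a

    @property
    def epsilon(self) -> float:
        """Timescale ratio tau_a / tau_b (0.2 at defaults)."""
        return self.tau_a / self.tau_b

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        sig = d.pop("sigmoid")
        d.update({f"sigmoid_{k}": v for k, v in sig.items()})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        sig = {k[len("sigmoid_"):]: d.pop(k)
               for k in list(d) if k.startswith("sigmoid_")}
        known = set(cls.__dataclass_fields__) - {"sigmoid"}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(sigmoid=SigmoidParams(**sig) if sig else SigmoidParams(), **d)


@dataclass(frozen=True)
class TimescaleParams:
    """Explicit timescale ratios used by the rescaled three-timescale system.

    ``delta = tau_g / tau_a`` separates the fast PV+ pair from the slow
    pyramidal quadruple; ``epsilon = tau_a / tau_b`` separates the slow
    quadruple from the superslow SOM+ pair.  When ``independent`` is true
    the pair (delta, epsilon) may be varied for singular-limit studies
    without touching the synaptic time constants themselves.
    """

    delta: float = 0.3
    epsilon: float = 0.2
    independent: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.delta <= 1) or not (0 < self.epsilon <= 1):
            raise ValueError("delta and epsilon must lie in (0, 1]")

    @classmethod
    def from_taus(cls, params: ModelParams) -> "TimescaleParams":
        return cls(delta=params.delta, epsilon=params.epsilon, independent=False)


@dataclass(frozen=True)
class StimCoupling:
    """Coupling coefficients routing an external input to each subpopulation.

    ``kP`` scales the input seen by the pyramidal populations, ``kSOM`` the
    SOM+ interneurons and ``kPV`` the PV+ interneurons; zero leaves the
    subpopulation unperturbed.
    """

    kP: float = 0.0
    kSOM: float = 0.0
    kPV: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kP", "kSOM", "kPV"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def is_zero(self) -> bool:
        return self.kP == 0.0 and self.kSOM == 0.0 and self.kPV == 0.0


_COUPLING_KEYS = ("kP", "kSOM", "kPV")


def save_params(path, params: ModelParams, coupling: StimCoupling | None = None) -> None:
    """Write parameters (and optionally couplings) as flat YAML/JSON key-value."""
    path = Path(path)
    d = params.to_dict()
    # drop sigmoid defaults from the flat file unless customised
    if params.sigmoid == SigmoidParams():
        for k in list(d):
            if k.startswith("sigmoid_"):
                del d[k]
    if coupling is not None:
        d.update({k: getattr(coupling, k) for k in _COUPLING_KEYS})
    text = (json.dumps(d, indent=2) if path.suffix == ".json"
            else yaml.safe_dump(d, sort_keys=False))
    path.write_text(text)


def load_params(path) -> tuple[ModelParams, StimCoupling]:
    """Read a flat YAML/JSON parameter file; unknown keys raise KeyError."""
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    coupling = StimCoupling(**{k: float(d.pop(k)) for k in _COUPLING_KEYS if k in d})
    return ModelParams.from_dict(d), coupling
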