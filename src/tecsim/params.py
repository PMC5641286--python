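"""Global parameter sets for network dynamics and ideomotor learning.

A single :class:`NetworkParams` instance governs every layer of a model: the
simulator deliberately has no per-layer or per-unit parameters, matching the
interactive-activation tradition where one global decay rate, gain and output
nonlinearity are shared by all coding units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import yaml

__all__ = ["NetworkParams", "LearningParams", "load_params", "dump_params"]


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the recurrent activation dynamics.

    Attributes
    ----------
    d_a:
        Activation decay rate per cycle, in [0, 1]. With zero input a unit's
        activation decays geometrically toward ``resting_level``.
    gamma:
        Global input gain applied to the net (excitatory + inhibitory) input.
    na, qa:
        Exponent and half-saturation constant of the sigmoid output function
        ``F(a) = a**na / (qa**na + a**na)``; ``F(qa) = 0.5``.
    VT:
        Voltage threshold in [0, 1). Top-down (voltage-dependent) input to a
        sensory unit is discarded while the unit's decayed activation
        ``a * (1 - d_a)`` lies at or below VT, so top-down input alone can
        never ignite a sensory code.
    noise_mean, noise_sd:
        Mean and SD of the Gaussian input noise drawn independently per
        excitatory unit per cycle. Inhibitory units receive no noise.
    ext_input:
        Magnitude of external stimulation delivered to a stimulated sensory
        unit (or to a directly driven motor unit during learning).
    response_threshold:
        Motor-unit activation that terminates a trial, in (0, 1].
    resting_level:
        Activation toward which units decay absent input (default 0).
    max_cycles:
        Hard cap on cycles per trial; trials that never cross the response
        threshold are reported as omissions at this length.
    """

    d_a: float = 0.082
    gamma: float = 0.3
    na: float = 6.0472
    qa: float = 0.5936
    VT: float = 0.3847
    noise_mean: float = 0.0
    noise_sd: float = 0.01
    ext_input: float = 0.991
    response_threshold: float = 0.7109
    resting_level: float = 0.0
    max_cycles: int = 250
    # lateral-competition wiring applied by the model builder
    w_exc_inh: float = 0.7523    # excitatory unit -> its paired inhibitory unit
    w_inh: float = -0.6981       # inhibitory unit -> competing excitatory units

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_a <= 1.0:
            raise ValueError(f"d_a must lie in [0, 1], got {self.d_a}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.na <= 0 or self.qa <= 0:
            raise ValueError("na and qa must be > 0")
        if not 0.0 <= self.VT < 1.0:
            raise ValueError(f"VT must lie in [0, 1), got {self.VT}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ext_input <= 0:
            raise ValueError("ext_input must be > 0")
        if not 0.0 < self.response_threshold <= 1.0:
            raise ValueError("response_threshold must lie in (0, 1]")
        if not 0.0 <= self.resting_level < 1.0:
            raise ValueError("resting_level must lie in [0, 1)")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if self.w_exc_inh < 0 or self.w_exc_inh > 1:
            raise ValueError("w_exc_inh must lie in [0, 1]")
        if self.w_inh > 0:
            raise ValueError("w_inh must be <= 0")

    def replace(self, **kwargs: Any) -> "NetworkParams":
        d = asdict(self)
        d.update(kwargs)
        return NetworkParams(**d)


@dataclass(frozen=True)
class LearningParams:
    """Parameters of the Hebbian action-effect learning phase.

    ``d_w`` is the weight decay per learning trial and ``LT`` the learning
    threshold: only the fraction of a unit's activation above LT (rescaled to
    [0, 1]) enters the Hebbian product, so weakly active codes do not learn.
    """

    d_w: float = 0.0819
    LT: float = 0.4818
    n_learning_trials: int = 20
    effect_cycles: int = 50
    clamp_motor: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_w <= 1.0:
            raise ValueError("d_w must lie in [0, 1]")
        if not 0.0 <= self.LT < 1.0:
            raise ValueError("LT must lie in [0, 1)")
        if self.n_learning_trials < 1 or self.effect_cycles < 1:
            raise ValueError("trial/cycle counts must be >= 1")

    def replace(self, **kwargs: Any) -> "LearningParams":
        d = asdict(self)
        d.update(kwargs)
        return LearningParams(**d)


def _from_mapping(cls, mapping: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {', '.join(unknown)}")
    return cls(**mapping)


def load_params(path: str | Path) -> tuple[NetworkParams, LearningParams]:
    """Load a flat or sectioned YAML/JSON parameter file.

    The file either holds two top-level sections ``network:`` and
    ``learning:`` or a flat map whose keys are routed to the owning
    dataclass. Unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must hold a mapping")
    if "network" in raw or "learning" in raw:
        extra = set(raw) - {"network", "learning"}
        if extra:
            raise ValueError(f"unknown top-level sections: {sorted(extra)}")
        net = _from_mapping(NetworkParams, raw.get("network") or {})
        learn = _from_mapping(LearningParams, raw.get("learning") or {})
        return net, learn
    net_keys = {f.name for f in fields(NetworkParams)}
    learn_keys = {f.name for f in fields(LearningParams)}
    unknown = sorted(set(raw) - net_keys - learn_keys)
    if unknown:
        raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
    net = _from_mapping(NetworkParams, {k: v for k, v in raw.items() if k in net_keys})
    learn = _from_mapping(LearningParams, {k: v for k, v in raw.items() if k in learn_keys})
    return net, learn


def dump_params(net: NetworkParams, learn: LearningParams, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"network": asdict(net), "learning": asdict(learn)}, sort_keys=False)
    )
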