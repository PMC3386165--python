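"""Run configuration: one YAML file holds every threshold and seed.

Unknown keys are rejected so silent typos cannot change an analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigurationError
from .modules import DEFAULT_SCALES

__all__ = ["RunConfig", "load_config"]


def _from_mapping(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown keys {sorted(unknown)} in section {cls.__name__}"
        )
    return cls(**data)


@dataclass
class NullConfig:
    n_perm: int = 20
    mode: str = "within_condition"

    def __post_init__(self):
        if self.n_perm < 1:
            raise ConfigurationError("null.n_perm must be >= 1")


@dataclass
class MixtureConfig:
    gamma_scale: float = 0.0
    prior_weights: list | None = None
    decomposition: str = "shifted"
    tol: float = 1e-6
    max_iter: int = 1000


@dataclass
class NetworkConfig:
    snr_cutoff: float = 10.0
    mean_condition: str | None = None
    prune_isolated: bool = False

    def __post_init__(self):
        if not self.snr_cutoff > 0:
            raise ConfigurationError("network.snr_cutoff must be > 0")


@dataclass
class ModulesConfig:
    scales: list = field(default_factory=lambda: list(DEFAULT_SCALES))
    B: int = 1000
    p_max: float = 0.05
    min_size: int = 5
    max_frac: float = 0.5
    density_min: float = 0.5
    effect_sign: str = "any"
    linkage: str = "average"

    def __post_init__(self):
        if self.min_size < 2:
            raise ConfigurationError("modules.min_size must be >= 2")
        if not all(0.5 <= s <= 1.4 for s in self.scales):
            raise ConfigurationError("modules.scales must lie within [0.5, 1.4]")


@dataclass
class SimulateConfig:
    rep_range: list = field(default_factory=lambda: [2, 4, 8])
    noise_range: list = field(default_factory=lambda: [0.25, 0.5, 0.75, 1.0])
    n_sims: int = 20
    model: str = "global"
    fpr: float = 0.0
    fnr: float = 0.0
    n_perm: int = 5
    n_genes: int = 100
    sizes: list = field(default_factory=lambda: [30, 30, 40])


@dataclass
class RunConfig:
    seed: int = 0
    null: NullConfig = field(default_factory=NullConfig)
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    modules: ModulesConfig = field(default_factory=ModulesConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "null": NullConfig,
    "mixture": MixtureConfig,
    "network": NetworkConfig,
    "modules": ModulesConfig,
    "simulate": SimulateConfig,
}


def load_config(path: str | None = None) -> RunConfig:
    """Load a RunConfig from YAML; missing sections take their defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    if None in data:  # YAML reads the bare section name "null" as None
        data["null"] = data.pop(None)
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigurationError(f"{path}: unknown top-level keys {sorted(unknown)}")
    kwargs = {"seed": int(data.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigurationError(f"{path}: section {name!r} must be a mapping")
        kwargs[name] = _from_mapping(cls, section)
    return RunConfig(**kwargs)
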