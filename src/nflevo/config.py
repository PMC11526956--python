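"""Run configuration: validation, presets, serialization, hashing.

A :class:`RunConfig` fully determines a simulation campaign given its
seed.  Named presets bundle the parameter regimes studied with the
model; the pathogen replication rate ``pi`` has **no default** in the
library — a config file must set it explicitly — but every shipped
preset pins it to 0.05 (see docs/methods.md for the rationale).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .dynamics import DynamicsParams
from .evolution import EvolutionConfig
from .genotypes import EDGES, HOST_PROTEINS, ConfigError

_FIELDS = {
    "n": int,
    "generations": int,
    "theta": float,
    "alpha": float,
    "beta": float,
    "MH": float,
    "MP": float,
    "L": int,
    "pi": float,
    "phi": None,  # float or mapping protein -> float
    "P0": float,
    "T": float,
    "dt": float,
    "force_inhibitory_IP": bool,
    "mu_overrides": None,  # mapping "R,P" -> float
    "sample_interval": int,
    "replicates": int,
    "seed": int,
    "out_dir": str,
    "log_level": str,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated union of evolution and dynamics parameters."""

    pi: float
    n: int = 2000
    generations: int = 20000
    theta: float = 1.0
    alpha: float = 2.0
    beta: float = 1.0
    MH: float = 0.001
    MP: float | None = None
    L: int = 10
    phi: float | Mapping[str, float] = 0.0
    P0: float = 1.0
    T: float = 1000.0
    dt: float = 1.0
    force_inhibitory_IP: bool = True
    mu_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sample_interval: int = 5
    replicates: int = 10
    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # range validation is delegated to the component configs
        self.evolution_config()
        if self.replicates < 1:
            raise ConfigError("replicates must be at least 1")

    def dynamics_params(self, infected: bool = True) -> DynamicsParams:
        return DynamicsParams(
            pi=self.pi,
            phi=self.phi,
            P0=self.P0,
            T=self.T,
            dt=self.dt,
            infected=infected,
            force_inhibitory_IP=self.force_inhibitory_IP,
        )

    def evolution_config(self, seed: int | None = None) -> EvolutionConfig:
        return EvolutionConfig(
            dynamics=self.dynamics_params(),
            n=self.n,
            generations=self.generations,
            theta=self.theta,
            alpha=self.alpha,
            beta=self.beta,
            MH=self.MH,
            MP=self.MP,
            L=self.L,
            mu_overrides=dict(self.mu_overrides),
            sample_interval=self.sample_interval,
            seed=self.seed if seed is None else seed,
        )

    def scaled(self, scale: float) -> "RunConfig":
        """Desk-scale convenience: multiplies n and generations only."""
        if scale <= 0:
            raise ConfigError("scale must be positive")
        return self.with_updates(
            n=max(2, int(round(self.n * scale))),
            generations=max(0, int(round(self.generations * scale))),
        )

    def with_updates(self, **kwargs) -> "RunConfig":
        data = self.to_dict()
        data.update(kwargs)
        return RunConfig.from_dict(data)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        data = asdict(self)
        data["mu_overrides"] = {
            f"{i},{j}": v for (i, j), v in self.mu_overrides.items()
        }
        if isinstance(self.phi, Mapping):
            data["phi"] = dict(self.phi)
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - set(_FIELDS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "pi" not in data or data["pi"] is None:
            raise ConfigError(
                "the pathogen replication rate 'pi' must be set explicitly; "
                "it is a modelling choice with no library default"
            )
        overrides = data.get("mu_overrides") or {}
        parsed: dict[tuple[str, str], float] = {}
        for key, value in overrides.items():
            edge = tuple(k.strip() for k in key.split(",")) if isinstance(key, str) else tuple(key)
            if edge not in EDGES:
                raise ConfigError(f"override names unknown edge {key!r}")
            parsed[edge] = float(value)
        data["mu_overrides"] = parsed
        phi = data.get("phi", 0.0)
        if isinstance(phi, Mapping):
            bad = set(phi) - set(HOST_PROTEINS)
            if bad:
                raise ConfigError(f"phi names unknown proteins: {sorted(bad)}")
            data["phi"] = {p: float(v) for p, v in phi.items()}
        return cls(**data)

    def config_hash(self) -> str:
        """Short provenance hash over all run-determining fields."""
        data = self.to_dict()
        data.pop("out_dir", None)
        data.pop("log_level", None)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:10]


#: Named parameter regimes.  All share pi=0.05, P0=1, T=1000, MH=0.001,
#: MP=2*MH, theta=1, n=2000 and 20000 generations unless stated.
PRESETS: dict[str, dict] = {
    # no protein degradation; infection twice as costly as response
    "baseline": {"pi": 0.05, "alpha": 2.0, "beta": 1.0, "phi": 0.0},
    # response as costly as infection
    "costly_response": {"pi": 0.05, "alpha": 2.0, "beta": 2.0, "phi": 0.0},
    # all proteins degrade; receptor pinned to full pathogen activation
    "degrading_proteins": {
        "pi": 0.05,
        "alpha": 2.0,
        "beta": 1.0,
        "phi": 0.15,
        "mu_overrides": {"R,P": 1.0},
    },
    # as above but the receptor itself does not degrade
    "stable_receptor": {
        "pi": 0.05,
        "alpha": 2.0,
        "beta": 1.0,
        "phi": {"R": 0.0, "A": 0.15, "I": 0.15, "U": 0.15, "D": 0.15},
        "mu_overrides": {"R,P": 1.0},
    },
    # stable receptor under incomplete infection
    "low_infection": {
        "pi": 0.05,
        "alpha": 2.0,
        "beta": 1.0,
        "theta": 0.7,
        "phi": {"R": 0.0, "A": 0.15, "I": 0.15, "U": 0.15, "D": 0.15},
        "mu_overrides": {"R,P": 1.0},
    },
    # same, with drift weakened by a larger population
    "low_infection_large": {
        "pi": 0.05,
        "alpha": 2.0,
        "beta": 1.0,
        "theta": 0.7,
        "n": 5000,
        "phi": {"R": 0.0, "A": 0.15, "I": 0.15, "U": 0.15, "D": 0.15},
        "mu_overrides": {"R,P": 1.0},
    },
    # stable receptor with a high response cost
    "costly_stable_receptor": {
        "pi": 0.05,
        "alpha": 2.0,
        "beta": 2.0,
        "phi": {"R": 0.0, "A": 0.15, "I": 0.15, "U": 0.15, "D": 0.15},
        "mu_overrides": {"R,P": 1.0},
    },
    # non-evolving pathogen, receptor free to adapt to it
    "frozen_pathogen": {
        "pi": 0.05,
        "alpha": 2.0,
        "beta": 1.0,
        "MP": 0.0,
        "phi": {"R": 0.0, "A": 0.15, "I": 0.15, "U": 0.15, "D": 0.15},
    },
}


def load_config(source: str | Path) -> RunConfig:
    """Load a RunConfig from a preset name or a YAML file path."""
    name = str(source)
    if name in PRESETS:
        return RunConfig.from_dict(PRESETS[name])
    path = Path(source)
    if not path.exists():
        raise ConfigError(
            f"{name!r} is neither a preset ({', '.join(sorted(PRESETS))}) "
            "nor an existing config file"
        )
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must hold a mapping")
    return RunConfig.from_dict(data)
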