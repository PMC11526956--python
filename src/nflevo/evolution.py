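"""Generational host–pathogen coevolution loop.

Each generation: hosts are randomly paired with pathogens and infected
with probability theta; within-host dynamics yield lifetime averages P̄
and Ī per infected host; host fitness is exp(−(alpha·P̄ + beta·Ī))
(uninfected hosts score exactly 1) and pathogen fitness is P̄ for a
pathogen that infected a host, 0 otherwise.  Parents are drawn
fitness-proportionally with replacement; hosts reproduce sexually (two
distinct parents, one recombination per protein) and pathogens
asexually.  Offspring mutate at rate MH (hosts) or MP (pathogens); both
populations are replaced wholesale, so the population size n is
conserved every generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams, batch_time_averages
from .genotypes import (
    DOMAINS,
    EDGES,
    HOST_PROTEINS,
    ConfigError,
    HostPopulation,
    PathogenPopulation,
    interaction_matrix,
    mutate_population,
    random_population,
    recombine_population,
)
from .rates import ConsensusTrack

#: Edges internal to the host genotype (independent of the pathogen partner).
HOST_EDGES = tuple(e for e in EDGES if "P" not in e)
#: Edges realized only by an actual host–pathogen pairing.
PAIR_EDGES = tuple(e for e in EDGES if "P" in e)


class DegeneratePopulationError(RuntimeError):
    """Raised when no individual has positive fitness."""


def edge_column(edge: tuple[str, str]) -> str:
    """TSV/DataFrame column name for a topology edge (target, source)."""
    return f"mu_{edge[0]}_{edge[1]}"


@dataclass(frozen=True)
class EvolutionConfig:
    """Run configuration of the coevolution simulation."""

    dynamics: DynamicsParams
    n: int = 2000
    generations: int = 20000
    theta: float = 1.0
    alpha: float = 2.0
    beta: float = 1.0
    MH: float = 0.001
    MP: float | None = None  # defaults to 2 * MH
    L: int = 10
    mu_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sample_interval: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("population size n must be at least 2")
        if self.generations < 0:
            raise ConfigError("generations must be non-negative")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigError("theta must lie in [0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("alpha and beta must be non-negative")
        if not 0.0 <= self.MH <= 1.0:
            raise ConfigError("MH must be a probability")
        if self.MP is not None and not 0.0 <= self.MP <= 1.0:
            raise ConfigError("MP must be a probability")
        if self.L < 2:
            raise ConfigError("L must be at least 2")
        for edge, value in self.mu_overrides.items():
            if tuple(edge) not in EDGES:
                raise ConfigError(f"override names unknown edge {edge}")
            if not -1.0 <= value <= 1.0:
                raise ConfigError(f"override mu{edge} = {value} outside [-1, 1]")

    @property
    def pathogen_rate(self) -> float:
        return 2.0 * self.MH if self.MP is None else self.MP


@dataclass
class PopulationState:
    hosts: HostPopulation
    pathogens: PathogenPopulation
    generation: int = 0


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation summary: the time series plotted over evolution."""

    generation: int
    mean_mu: Mapping[tuple[str, str], float]
    mean_host_fitness: float
    mean_pathogen_fitness: float
    fraction_infected: float

    def as_row(self) -> dict:
        row = {"generation": self.generation}
        row.update({edge_column(e): self.mean_mu[e] for e in EDGES})
        row["mean_host_fitness"] = self.mean_host_fitness
        row["mean_pathogen_fitness"] = self.mean_pathogen_fitness
        row["fraction_infected"] = self.fraction_infected
        return row


@dataclass
class Pairing:
    """Random one-to-one host–pathogen assignment with infection draws.

    ``pathogen_of[h]`` is the index of the pathogen encountered by host
    h; ``infected[h]`` says whether the encounter became an infection.
    """

    hosts: HostPopulation
    pathogens: PathogenPopulation
    pathogen_of: np.ndarray
    infected: np.ndarray

    def __iter__(self) -> Iterator[tuple]:
        for h in range(len(self.hosts)):
            partner = (
                self.pathogens[int(self.pathogen_of[h])] if self.infected[h] else None
            )
            yield self.hosts[h], partner

    @property
    def infected_hosts(self) -> np.ndarray:
        return np.nonzero(self.infected)[0]


def pair_and_infect(
    hosts: HostPopulation,
    pathogens: PathogenPopulation,
    theta: float,
    rng: np.random.Generator,
) -> Pairing:
    """Permute pathogens against hosts, then realize infections at theta."""
    if len(hosts) != len(pathogens):
        raise ConfigError("host and pathogen populations must have equal size")
    n = len(hosts)
    perm = rng.permutation(n)
    infected = rng.random(n) < theta
    return Pairing(hosts, pathogens, perm, infected)


def host_fitness(P_bar, I_bar, alpha: float, beta: float):
    """exp(−(alpha·P̄ + beta·Ī)); accepts scalars or arrays.

    Uninfected hosts bypass this and receive fitness exactly 1.
    """
    P_bar = np.asarray(P_bar, dtype=float)
    I_bar = np.asarray(I_bar, dtype=float)
    if (P_bar < 0).any() or (I_bar < 0).any():
        raise ValueError("lifetime averages must be non-negative")
    out = np.exp(-(alpha * P_bar + beta * I_bar))
    return float(out) if out.ndim == 0 else out


def pathogen_fitness(P_bar, infected):
    """P̄ for a pathogen that infected a host, 0 otherwise."""
    P_bar = np.asarray(P_bar, dtype=float)
    out = np.where(infected, P_bar, 0.0)
    return float(out) if out.ndim == 0 else out


def select_parents(
    fitnesses: np.ndarray,
    k: int,
    rng: np.random.Generator,
    pairs: bool = False,
) -> np.ndarray:
    """Fitness-proportional multinomial parent sampling with replacement.

    Returns a (k,) index array, or a (2, k) array of two *distinct*
    parents per offspring when ``pairs`` is true (sexual reproduction).
    """
    w = np.asarray(fitnesses, dtype=float)
    if (w < 0).any():
        raise ValueError("fitnesses must be non-negative")
    positive = int(np.count_nonzero(w))
    if positive == 0:
        raise DegeneratePopulationError("all fitnesses are zero")
    if pairs and positive < 2:
        raise DegeneratePopulationError(
            "sexual reproduction needs two distinct viable parents"
        )
    p = w / w.sum()
    n = w.size
    first = rng.choice(n, size=k, p=p)
    if not pairs:
        return first
    second = rng.choice(n, size=k, p=p)
    clash = first == second
    while clash.any():
        second[clash] = rng.choice(n, size=int(clash.sum()), p=p)
        clash = first == second
    return np.stack([first, second])


def step_generation(
    state: PopulationState, config: EvolutionConfig, rng: np.random.Generator
) -> tuple[PopulationState, GenerationRecord]:
    """Advance one generation; returns the new state and its record."""
    gen = state.generation
    try:
        return _step(state, config, rng)
    except DegeneratePopulationError as err:
        raise DegeneratePopulationError(f"generation {gen}: {err}") from err


def _step(state, config, rng):
    hosts, pathogens = state.hosts, state.pathogens
    n = len(hosts)
    pairing = pair_and_infect(hosts, pathogens, config.theta, rng)
    inf = pairing.infected_hosts
    pat = pairing.pathogen_of[inf]

    host_w = np.ones(n)
    pat_w = np.zeros(n)
    if inf.size:
        mu_pairs = interaction_matrix(
            hosts.bits[inf], pathogens.bits[pat], config.mu_overrides
        )
        infected_params = replace(config.dynamics, infected=True)
        P_bar, I_bar = batch_time_averages(mu_pairs, infected_params)
        host_w[inf] = host_fitness(P_bar, I_bar, config.alpha, config.beta)
        pat_w[pat] = pathogen_fitness(P_bar, True)

    # population-mean mu per edge: host-internal edges over all hosts,
    # pathogen-facing edges over realized pairings only
    mean_mu: dict[tuple[str, str], float] = {}
    mu_host = interaction_matrix(
        hosts.bits, pathogens.bits, config.mu_overrides, edges=HOST_EDGES
    )
    for k, edge in enumerate(HOST_EDGES):
        mean_mu[edge] = float(mu_host[:, k].mean())
    for edge in PAIR_EDGES:
        mean_mu[edge] = (
            float(mu_pairs[:, EDGES.index(edge)].mean()) if inf.size else float("nan")
        )

    # hosts: sexual reproduction from two distinct parents
    parents = select_parents(host_w, n, rng, pairs=True)
    offspring = recombine_population(
        hosts.bits[parents[0]], hosts.bits[parents[1]], rng
    )
    offspring = mutate_population(offspring, config.MH, rng)

    # pathogens: asexual; with zero realized infections the whole
    # population has fitness 0 and reproduces by pure drift
    if pat_w.sum() > 0:
        pat_parents = select_parents(pat_w, n, rng)
    else:
        pat_parents = rng.integers(0, n, size=n)
    pat_offspring = mutate_population(
        pathogens.bits[pat_parents], config.pathogen_rate, rng
    )

    record = GenerationRecord(
        generation=state.generation + 1,
        mean_mu=mean_mu,
        mean_host_fitness=float(host_w.mean()),
        mean_pathogen_fitness=float(pat_w.mean()),
        fraction_infected=float(inf.size / n),
    )
    new_state = PopulationState(
        HostPopulation(offspring),
        PathogenPopulation(pat_offspring),
        state.generation + 1,
    )
    return new_state, record


def _host_consensus(hosts: HostPopulation) -> dict:
    c = hosts.bits.mean(axis=0)  # (5, 3, L)
    return {
        (p, d): c[pi, di]
        for pi, p in enumerate(HOST_PROTEINS)
        for di, d in enumerate(DOMAINS)
    }


@dataclass
class RunResult:
    """Everything produced by one replicate simulation."""

    config: EvolutionConfig
    records: list
    hosts: HostPopulation
    pathogens: PathogenPopulation
    track: ConsensusTrack

    def record_frame(self) -> pd.DataFrame:
        columns = (
            ["generation"]
            + [edge_column(e) for e in EDGES]
            + ["mean_host_fitness", "mean_pathogen_fitness", "fraction_infected"]
        )
        return pd.DataFrame([r.as_row() for r in self.records], columns=columns)

    def omega_frame(self) -> pd.DataFrame:
        return self.track.to_frame()


def run(config: EvolutionConfig, rng: np.random.Generator | None = None) -> RunResult:
    """Run one replicate from a random initial population.

    Fully reproducible from (config, config.seed); pass ``rng`` to
    override the seed-derived generator (e.g. replicate sub-streams).
    The consensus tracker samples every ``sample_interval`` generations,
    starting with the focal consensus at generation 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    hosts, pathogens = random_population(config.n, config.L, rng)
    state = PopulationState(hosts, pathogens, 0)
    track = ConsensusTrack(sample_interval=config.sample_interval)
    track.update(_host_consensus(hosts), 0)
    records: list[GenerationRecord] = []
    for _ in range(config.generations):
        state, record = step_generation(state, config, rng)
        records.append(record)
        if state.generation % config.sample_interval == 0:
            track.update(_host_consensus(state.hosts), state.generation)
    return RunResult(config, records, state.hosts, state.pathogens, track)
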