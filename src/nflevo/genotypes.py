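"""Bit-string genotypes and Hamming-distance interaction coefficients.

Hosts carry five signaling proteins — R (receptor), A (activator),
I (immunity), U (upstream regulator), D (downstream regulator) — and the
pathogen carries a single protein P.  Each protein consists of three
L-bit domains: a *receiver* domain through which it is regulated, a
*sender* domain through which it acts on other proteins, and a *neutral*
domain that takes part in no interaction and serves as the benchmark for
the neutral rate of evolution.

The signed strength of a directed interaction j → i is a function of the
Hamming distance H between the sender domain of the acting protein j and
the receiver domain of the target protein i::

    mu_{i,j} = 1 - 2 H / L

so identical domains give full activation (+1), complementary domains
full inhibition (−1), and exactly L/2 mismatches no interaction (0).

Populations are stored as dense ``uint8`` bit arrays so that whole-
population operations (interaction matrices, recombination, mutation,
consensus) are vectorized; the dataclass wrappers below give tests and
user code a typed, validated view of single individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Host protein labels, in fixed storage order.
HOST_PROTEINS: tuple[str, ...] = ("R", "A", "I", "U", "D")

#: Domain names in fixed storage order (axis index within a protein).
DOMAINS: tuple[str, ...] = ("receiver", "neutral", "sender")

RECEIVER, NEUTRAL, SENDER = 0, 1, 2

#: Directed potential interactions (target i, source j) of the signaling
#: network: the pathogen activates the receptor, R engages A, A engages
#: I and both regulators, U feeds back on R, D feeds back on I, and I
#: acts on the pathogen.
EDGES: tuple[tuple[str, str], ...] = (
    ("R", "P"),
    ("A", "R"),
    ("I", "A"),
    ("U", "A"),
    ("D", "A"),
    ("R", "U"),
    ("I", "D"),
    ("P", "I"),
)

_HOST_INDEX = {label: k for k, label in enumerate(HOST_PROTEINS)}

DEFAULT_L = 10


class DimensionError(ValueError):
    """Raised when bit domains of unequal length are combined."""


@dataclass(frozen=True)
class BitDomain:
    """One L-bit domain of a protein.

    Parameters
    ----------
    sites
        Ordered 0/1 values; site 1 is the leftmost position.
    """

    sites: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.sites, dtype=np.uint8)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("a bit domain is a non-empty 1-D vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("bit domain sites must be 0 or 1")
        object.__setattr__(self, "sites", arr)

    @property
    def L(self) -> int:
        return int(self.sites.size)

    @classmethod
    def from_string(cls, bits: str) -> "BitDomain":
        return cls(np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))

    def __str__(self) -> str:
        return "".join("1" if b else "0" for b in self.sites)


@dataclass(frozen=True)
class ProteinGene:
    """Three-domain gene for one protein of a host or the pathogen."""

    receiver: BitDomain
    neutral: BitDomain
    sender: BitDomain
    label: str

    def __post_init__(self) -> None:
        if self.label not in (*HOST_PROTEINS, "P"):
            raise ValueError(f"unknown protein label {self.label!r}")
        if not (self.receiver.L == self.neutral.L == self.sender.L):
            raise DimensionError("all three domains must share the same L")

    @property
    def L(self) -> int:
        return self.receiver.L

    def as_array(self) -> np.ndarray:
        """(3, L) uint8 array in domain order receiver, neutral, sender."""
        return np.stack(
            [self.receiver.sites, self.neutral.sites, self.sender.sites]
        )

    @classmethod
    def from_array(cls, bits: np.ndarray, label: str) -> "ProteinGene":
        return cls(
            BitDomain(bits[RECEIVER]),
            BitDomain(bits[NEUTRAL]),
            BitDomain(bits[SENDER]),
            label,
        )


@dataclass(frozen=True)
class HostGenotype:
    """The five host proteins keyed R, A, I, U, D."""

    proteins: Mapping[str, ProteinGene]

    def __post_init__(self) -> None:
        if set(self.proteins) != set(HOST_PROTEINS):
            raise ValueError(f"host proteins must be exactly {HOST_PROTEINS}")
        Ls = {g.L for g in self.proteins.values()}
        if len(Ls) != 1:
            raise DimensionError("host proteins must share the same L")
        for label, gene in self.proteins.items():
            if gene.label != label:
                raise ValueError(f"protein keyed {label!r} has label {gene.label!r}")

    @property
    def L(self) -> int:
        return self.proteins["R"].L

    def as_array(self) -> np.ndarray:
        """(5, 3, L) uint8 array in protein order R, A, I, U, D."""
        return np.stack([self.proteins[p].as_array() for p in HOST_PROTEINS])

    @classmethod
    def from_array(cls, bits: np.ndarray) -> "HostGenotype":
        return cls(
            {
                p: ProteinGene.from_array(bits[k], p)
                for k, p in enumerate(HOST_PROTEINS)
            }
        )


@dataclass(frozen=True)
class PathogenGenotype:
    """The pathogen's single protein P."""

    protein: ProteinGene

    def __post_init__(self) -> None:
        if self.protein.label != "P":
            raise ValueError("pathogen protein must be labelled P")

    @property
    def L(self) -> int:
        return self.protein.L

    def as_array(self) -> np.ndarray:
        """(3, L) uint8 array in domain order receiver, neutral, sender."""
        return self.protein.as_array()

    @classmethod
    def from_array(cls, bits: np.ndarray) -> "PathogenGenotype":
        return cls(ProteinGene.from_array(bits, "P"))


@dataclass(frozen=True)
class Topology:
    """The fixed directed edge set of the signaling network.

    Edges are (target i, source j) pairs; the set is immutable during a
    run.  The default is the full potential wiring described above.
    """

    edges: tuple[tuple[str, str], ...] = EDGES

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in topology")
        valid = set(HOST_PROTEINS) | {"P"}
        for i, j in self.edges:
            if i not in valid or j not in valid:
                raise ValueError(f"unknown protein in edge ({i},{j})")

    def index(self, edge: tuple[str, str]) -> int:
        return self.edges.index(edge)


@dataclass(frozen=True)
class InteractionState:
    """Current interaction coefficients, one per topology edge."""

    mu: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for edge, value in self.mu.items():
            if not -1.0 <= value <= 1.0:
                raise ValueError(f"mu{edge} = {value} outside [-1, 1]")

    def __getitem__(self, edge: tuple[str, str]) -> float:
        return self.mu[edge]


# ---------------------------------------------------------------------------
# Interaction coefficients


def hamming_distance(a: BitDomain, b: BitDomain) -> int:
    """Number of sites at which two equal-length domains differ."""
    if a.L != b.L:
        raise DimensionError(f"domain lengths differ: {a.L} != {b.L}")
    return int(np.count_nonzero(a.sites != b.sites))


def interaction_coefficient(
    sender_domain: BitDomain, receiver_domain: BitDomain
) -> float:
    """Signed interaction strength mu = 1 - 2H/L in [-1, 1].

    ``sender_domain`` belongs to the acting protein j, ``receiver_domain``
    to the target protein i.  Positive values are activatory, negative
    inhibitory; exactly L/2 mismatches yield 0 (no interaction).
    """
    H = hamming_distance(sender_domain, receiver_domain)
    return 1.0 - 2.0 * H / sender_domain.L


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


def _domain_of(
    label: str, which: int, host: HostGenotype, pathogen: PathogenGenotype
) -> BitDomain:
    gene = pathogen.protein if label == "P" else host.proteins[label]
    return (gene.receiver, gene.neutral, gene.sender)[which]


def compute_interactions(
    host: HostGenotype,
    pathogen: PathogenGenotype,
    topology: Topology = Topology(),
    overrides: Mapping[tuple[str, str], float] | None = None,
) -> InteractionState:
    """Interaction coefficients for one host–pathogen pairing.

    For each topology edge (i, j) the coefficient is computed from the
    sender domain of j and the receiver domain of i, except edges listed
    in ``overrides``, which take the fixed value verbatim (used e.g. to
    pin the receptor–pathogen interaction at 1 so the receptor does not
    co-evolve with the pathogen).
    """
    overrides = dict(overrides or {})
    for edge, value in overrides.items():
        if not -1.0 <= value <= 1.0:
            raise ConfigError(f"override mu{edge} = {value} outside [-1, 1]")
    if host.L != pathogen.L:
        raise DimensionError("host and pathogen must share L")
    mu: dict[tuple[str, str], float] = {}
    for i, j in topology.edges:
        if (i, j) in overrides:
            mu[(i, j)] = float(overrides[(i, j)])
        else:
            mu[(i, j)] = interaction_coefficient(
                _domain_of(j, SENDER, host, pathogen),
                _domain_of(i, RECEIVER, host, pathogen),
            )
    return InteractionState(mu)


def interaction_matrix(
    host_bits: np.ndarray,
    pathogen_bits: np.ndarray,
    overrides: Mapping[tuple[str, str], float] | None = None,
    edges: Sequence[tuple[str, str]] = EDGES,
) -> np.ndarray:
    """Vectorized interaction coefficients for paired populations.

    Parameters
    ----------
    host_bits
        ``(m, 5, 3, L)`` uint8 array of paired hosts.
    pathogen_bits
        ``(m, 3, L)`` uint8 array of the pathogens infecting them.

    Returns
    -------
    ``(m, len(edges))`` float64 matrix of mu values in edge order.
    """
    overrides = dict(overrides or {})
    m, L = host_bits.shape[0], host_bits.shape[-1]
    out = np.empty((m, len(edges)), dtype=np.float64)
    for k, (i, j) in enumerate(edges):
        if (i, j) in overrides:
            value = float(overrides[(i, j)])
            if not -1.0 <= value <= 1.0:
                raise ConfigError(f"override mu{(i, j)} = {value} outside [-1, 1]")
            out[:, k] = value
            continue
        snd = (
            pathogen_bits[:, SENDER, :]
            if j == "P"
            else host_bits[:, _HOST_INDEX[j], SENDER, :]
        )
        rcv = (
            pathogen_bits[:, RECEIVER, :]
            if i == "P"
            else host_bits[:, _HOST_INDEX[i], RECEIVER, :]
        )
        H = np.count_nonzero(snd != rcv, axis=1)
        out[:, k] = 1.0 - 2.0 * H / L
    return out


# ---------------------------------------------------------------------------
# Populations


class HostPopulation(Sequence):
    """A host population stored as an (n, 5, 3, L) uint8 bit array."""

    def __init__(self, bits: np.ndarray):
        bits = np.ascontiguousarray(bits, dtype=np.uint8)
        if bits.ndim != 4 or bits.shape[1] != 5 or bits.shape[2] != 3:
            raise ValueError("host population bits must be (n, 5, 3, L)")
        self.bits = bits

    def __len__(self) -> int:
        return self.bits.shape[0]

    def __getitem__(self, k):
        if isinstance(k, slice):
            return HostPopulation(self.bits[k])
        return HostGenotype.from_array(self.bits[k])

    @property
    def L(self) -> int:
        return self.bits.shape[-1]

    @classmethod
    def from_genotypes(cls, genotypes: Iterable[HostGenotype]) -> "HostPopulation":
        return cls(np.stack([g.as_array() for g in genotypes]))


class PathogenPopulation(Sequence):
    """A pathogen population stored as an (n, 3, L) uint8 bit array."""

    def __init__(self, bits: np.ndarray):
        bits = np.ascontiguousarray(bits, dtype=np.uint8)
        if bits.ndim != 3 or bits.shape[1] != 3:
            raise ValueError("pathogen population bits must be (n, 3, L)")
        self.bits = bits

    def __len__(self) -> int:
        return self.bits.shape[0]

    def __getitem__(self, k):
        if isinstance(k, slice):
            return PathogenPopulation(self.bits[k])
        return PathogenGenotype.from_array(self.bits[k])

    @property
    def L(self) -> int:
        return self.bits.shape[-1]

    @classmethod
    def from_genotypes(
        cls, genotypes: Iterable[PathogenGenotype]
    ) -> "PathogenPopulation":
        return cls(np.stack([g.as_array() for g in genotypes]))


def random_population(
    n: int, L: int, rng: np.random.Generator
) -> tuple[HostPopulation, PathogenPopulation]:
    """n random hosts and n random pathogens, bits i.i.d. Bernoulli(0.5)."""
    if n < 2:
        raise ConfigError("population size must be at least 2")
    hosts = rng.integers(0, 2, size=(n, 5, 3, L), dtype=np.uint8)
    pathogens = rng.integers(0, 2, size=(n, 3, L), dtype=np.uint8)
    return HostPopulation(hosts), PathogenPopulation(pathogens)


def consensus(domains) -> np.ndarray:
    """Per-site mean of bit values across a population of one domain.

    Accepts a list of :class:`BitDomain` or an ``(n, L)`` array; returns
    a length-L vector of 1-frequencies in [0, 1].
    """
    if isinstance(domains, np.ndarray):
        arr = domains
    else:
        domains = list(domains)
        if len(domains) == 0:
            raise ValueError("consensus of an empty population is undefined")
        arr = np.stack(
            [d.sites if isinstance(d, BitDomain) else np.asarray(d) for d in domains]
        )
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("consensus needs a non-empty (n, L) population")
    return arr.mean(axis=0)


# ---------------------------------------------------------------------------
# Recombination and mutation


def recombine_population(
    bits1: np.ndarray, bits2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sexual reproduction of hosts, vectorized over offspring.

    ``bits1`` and ``bits2`` are (m, 5, 3, L) arrays of first and second
    parents.  For each offspring and each protein independently, one
    domain and a cut site k within it (1-based, uniform on 1..L-1) are
    chosen; in that domain sites left of k come from parent 1 and sites
    from k rightward come from parent 2.  Each non-recombining domain is
    inherited whole from a uniformly chosen parent.
    """
    m, _, _, L = bits1.shape
    if bits1.shape != bits2.shape:
        raise DimensionError("parent arrays must have identical shape")
    # which domain recombines, per (offspring, protein)
    rec_domain = rng.integers(0, 3, size=(m, 5))
    # 0-based cut: k-1 for k uniform on 1..L-1
    cut = rng.integers(0, L - 1, size=(m, 5))
    whole_from_p2 = rng.random(size=(m, 5, 3)) < 0.5

    sites = np.arange(L)
    take_p2_rec = sites[None, None, :] >= cut[:, :, None]          # (m, 5, L)
    is_rec = rec_domain[:, :, None] == np.arange(3)[None, None, :]  # (m, 5, 3)
    take_p2 = np.where(
        is_rec[..., None],
        take_p2_rec[:, :, None, :],
        whole_from_p2[..., None],
    )
    return np.where(take_p2, bits2, bits1).astype(np.uint8)


def recombine_host(
    parent1: HostGenotype, parent2: HostGenotype, rng: np.random.Generator
) -> HostGenotype:
    """One sexual offspring from two host parents (see recombine_population)."""
    if parent1.L != parent2.L:
        raise DimensionError("parents must share L")
    child = recombine_population(
        parent1.as_array()[None], parent2.as_array()[None], rng
    )
    return HostGenotype.from_array(child[0])


def mutate_population(
    bits: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-individual single-bit mutation at probability ``rate``.

    With probability ``rate`` an individual gets exactly one bit flipped
    at a uniformly chosen position over all its domains (the neutral
    domain included — it is the neutral-rate benchmark).  Works for host
    (n, 5, 3, L) and pathogen (n, 3, L) arrays alike.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be a probability")
    n = bits.shape[0]
    flat = bits.reshape(n, -1).copy()
    hit = rng.random(n) < rate
    if hit.any():
        pos = rng.integers(0, flat.shape[1], size=int(hit.sum()))
        idx = np.nonzero(hit)[0]
        flat[idx, pos] ^= 1
    return flat.reshape(bits.shape)


def mutate(genotype, rate: float, rng: np.random.Generator):
    """Single-bit mutation of one genotype; returns the same type."""
    bits = mutate_population(genotype.as_array()[None], rate, rng)[0]
    if isinstance(genotype, HostGenotype):
        return HostGenotype.from_array(bits)
    if isinstance(genotype, PathogenGenotype):
        return PathogenGenotype.from_array(bits)
    raise TypeError(f"cannot mutate {type(genotype).__name__}")
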