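"""Bit-string genotypes, interaction coefficients, recombination, mutation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nflevo.genotypes import (
    DOMAINS,
    EDGES,
    HOST_PROTEINS,
    NEUTRAL,
    BitDomain,
    ConfigError,
    DimensionError,
    HostGenotype,
    Topology,
    compute_interactions,
    consensus,
    hamming_distance,
    interaction_coefficient,
    interaction_matrix,
    mutate,
    mutate_population,
    random_population,
    recombine_host,
    recombine_population,
)

from conftest import random_host, random_pathogen


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("1010110100", "1010110100", 0),
            ("1111100000", "0000011111", 10),
            ("1111100000", "1111111111", 5),
            ("10", "01", 2),
        ],
    )
    def test_examples(self, a, b, expected):
        assert hamming_distance(BitDomain.from_string(a), BitDomain.from_string(b)) == expected

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            hamming_distance(BitDomain.from_string("101"), BitDomain.from_string("10"))


class TestInteractionCoefficient:
    def test_full_table_strictly_decreasing(self):
        """mu = 1 - 2H/L is exact and strictly decreasing over H = 0..L."""
        L = 10
        base = BitDomain(np.zeros(L, dtype=np.uint8))
        values = []
        for H in range(L + 1):
            other = np.zeros(L, dtype=np.uint8)
            other[:H] = 1
            mu = interaction_coefficient(base, BitDomain(other))
            assert mu == pytest.approx(1 - 2 * H / L, abs=0)
            values.append(mu)
        assert all(x > y for x, y in zip(values, values[1:]))
        assert values[0] == 1.0 and values[5] == 0.0 and values[-1] == -1.0

    def test_neutral_domain_never_read(self, rng):
        """Mutating only neutral bits leaves every interaction unchanged."""
        host, pathogen = random_host(rng), random_pathogen(rng)
        before = compute_interactions(host, pathogen)
        hb, pb = host.as_array(), pathogen.as_array()
        hb[:, NEUTRAL, :] ^= 1
        pb[NEUTRAL, :] ^= 1
        from nflevo.genotypes import PathogenGenotype

        after = compute_interactions(
            HostGenotype.from_array(hb), PathogenGenotype.from_array(pb)
        )
        for edge in EDGES:
            assert before[edge] == after[edge]


class TestComputeInteractions:
    def test_identical_domains_give_full_activation(self, rng):
        from nflevo.genotypes import PathogenGenotype

        bits = np.tile(rng.integers(0, 2, size=10, dtype=np.uint8), (5, 3, 1))
        host = HostGenotype.from_array(bits)
        pathogen = PathogenGenotype.from_array(bits[0])
        state = compute_interactions(host, pathogen)
        assert all(state[e] == 1.0 for e in EDGES)

    def test_override_is_verbatim(self, rng):
        host, pathogen = random_host(rng), random_pathogen(rng)
        state = compute_interactions(host, pathogen, overrides={("R", "P"): 1.0})
        assert state[("R", "P")] == 1.0

    def test_override_out_of_range_rejected(self, rng):
        with pytest.raises(ConfigError):
            compute_interactions(
                random_host(rng), random_pathogen(rng), overrides={("R", "P"): 1.5}
            )

    def test_matches_bruteforce_per_edge(self, rng):
        """Every edge equals a raw-bit recomputation, scalar and vectorized."""
        host, pathogen = random_host(rng), random_pathogen(rng)
        state = compute_interactions(host, pathogen)
        hb, pb = host.as_array(), pathogen.as_array()
        pidx = {p: k for k, p in enumerate(HOST_PROTEINS)}
        mat = interaction_matrix(hb[None], pb[None])
        for col, (i, j) in enumerate(EDGES):
            snd = pb[2] if j == "P" else hb[pidx[j], 2]
            rcv = pb[0] if i == "P" else hb[pidx[i], 0]
            expected = 1 - 2 * int((snd != rcv).sum()) / 10
            assert state[(i, j)] == pytest.approx(expected, abs=0)
            assert mat[0, col] == pytest.approx(expected, abs=0)


class TestTopology:
    def test_default_edge_set(self):
        assert set(Topology().edges) == {
            ("R", "P"), ("A", "R"), ("I", "A"), ("U", "A"),
            ("D", "A"), ("R", "U"), ("I", "D"), ("P", "I"),
        }

    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError):
            Topology((("R", "P"), ("R", "P")))


class _ScriptedRng:
    """Plays back fixed draws for recombination-convention tests."""

    def __init__(self, rec_domain, cut, whole):
        self._rec, self._cut, self._whole = rec_domain, cut, whole
        self._int_calls = 0

    def integers(self, low, high, size):
        out = self._rec if self._int_calls == 0 else self._cut
        self._int_calls += 1
        return np.broadcast_to(np.asarray(out), size).copy()

    def random(self, size):
        return np.broadcast_to(np.asarray(self._whole), size).copy()


class TestRecombination:
    def test_identical_parents_reproduce_exactly(self, rng):
        host = random_host(rng)
        child = recombine_host(host, host, rng)
        assert np.array_equal(child.as_array(), host.as_array())

    def test_cut_at_first_site_copies_domain_from_parent2(self):
        """k = 1 means the whole recombining domain comes from parent 2."""
        p1 = HostGenotype.from_array(np.zeros((5, 3, 10), dtype=np.uint8))
        p2 = HostGenotype.from_array(np.ones((5, 3, 10), dtype=np.uint8))
        # recombine domain 0 with 0-based cut 0 (k=1); whole domains from p1
        scripted = _ScriptedRng(rec_domain=0, cut=0, whole=0.9)
        child = recombine_host(p1, p2, scripted)
        bits = child.as_array()
        assert (bits[:, 0, :] == 1).all()      # recombined: entirely parent 2
        assert (bits[:, 1:, :] == 0).all()     # inherited whole from parent 1

    def test_provenance_and_block_structure(self, rng):
        """Offspring sites always come from a parent at the same position,
        and each domain is a parent1-block followed by a parent2-block."""
        n = 1000
        b1 = np.zeros((n, 5, 3, 10), dtype=np.uint8)
        b2 = np.ones((n, 5, 3, 10), dtype=np.uint8)
        child = recombine_population(b1, b2, rng)
        assert child.shape == b1.shape
        assert np.isin(child, (0, 1)).all()  # provenance: 0 from p1, 1 from p2
        diffs = np.diff(child.astype(int), axis=-1)
        assert (diffs >= 0).all()  # within a domain p1 sites precede p2 sites
        # the recombination cut k <= L-1 leaves at least two parent-2 sites
        per_domain_ones = child.sum(axis=-1)
        assert np.isin(per_domain_ones, (0, 10) + tuple(range(2, 10))).all()

    def test_provenance_with_distinct_random_parents(self, rng):
        b1 = rng.integers(0, 2, size=(200, 5, 3, 10), dtype=np.uint8)
        b2 = rng.integers(0, 2, size=(200, 5, 3, 10), dtype=np.uint8)
        child = recombine_population(b1, b2, rng)
        assert ((child == b1) | (child == b2)).all()


class TestMutation:
    def test_rate_zero_is_identity(self, rng):
        host = random_host(rng)
        assert np.array_equal(mutate(host, 0.0, rng).as_array(), host.as_array())

    def test_rate_one_flips_exactly_one_bit(self, rng):
        for genotype in (random_host(rng), random_pathogen(rng)):
            mutant = mutate(genotype, 1.0, rng)
            assert int((mutant.as_array() != genotype.as_array()).sum()) == 1

    def test_hamming_change_is_zero_or_one(self, rng):
        bits = rng.integers(0, 2, size=(500, 5, 3, 10), dtype=np.uint8)
        out = mutate_population(bits, 0.5, rng)
        flips = (out != bits).reshape(500, -1).sum(axis=1)
        assert set(np.unique(flips)) <= {0, 1}

    def test_monte_carlo_rate(self, rng):
        """Fraction of mutated offspring matches the rate within binomial error."""
        n, rate = 100_000, 0.001
        bits = np.zeros((n, 3, 10), dtype=np.uint8)
        out = mutate_population(bits, rate, rng)
        hits = int((out != bits).any(axis=(1, 2)).sum())
        sd = np.sqrt(n * rate * (1 - rate))
        assert abs(hits - n * rate) < 5 * sd


class TestRandomPopulation:
    def test_shapes_and_site_frequencies(self, rng):
        hosts, pathogens = random_population(2000, 10, rng)
        assert hosts.bits.shape == (2000, 5, 3, 10)
        assert pathogens.bits.shape == (2000, 3, 10)
        freq = hosts.bits.mean(axis=0)
        sd = 0.5 / np.sqrt(2000)
        assert (np.abs(freq - 0.5) < 5 * sd).all()

    def test_seed_determinism(self):
        a = random_population(50, 10, np.random.default_rng(7))
        b = random_population(50, 10, np.random.default_rng(7))
        assert np.array_equal(a[0].bits, b[0].bits)
        assert np.array_equal(a[1].bits, b[1].bits)

    def test_too_small_population_rejected(self, rng):
        with pytest.raises(ConfigError):
            random_population(1, 10, rng)


class TestConsensus:
    def test_degenerate_and_mixed_populations(self):
        ones = np.ones((4, 10), dtype=np.uint8)
        assert (consensus(ones) == 1.0).all()
        half = np.vstack([np.zeros((2, 10)), np.ones((2, 10))]).astype(np.uint8)
        assert (consensus(half) == 0.5).all()

    def test_matches_mean_and_order_invariant(self, rng):
        arr = rng.integers(0, 2, size=(101, 10), dtype=np.uint8)
        np.testing.assert_allclose(consensus(arr), arr.mean(axis=0))
        perm = rng.permutation(101)
        np.testing.assert_array_equal(consensus(arr), consensus(arr[perm]))

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            consensus([])


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2**30))
def test_interaction_matrix_agrees_with_scalar_path(seed):
    rng = np.random.default_rng(seed)
    host, pathogen = random_host(rng), random_pathogen(rng)
    state = compute_interactions(host, pathogen)
    mat = interaction_matrix(host.as_array()[None], pathogen.as_array()[None])
    for col, edge in enumerate(EDGES):
        assert mat[0, col] == state[edge]
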