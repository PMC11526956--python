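import numpy as np
import pytest

from nflevo.genotypes import (
    BitDomain,
    HostGenotype,
    PathogenGenotype,
    ProteinGene,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def gene_from_strings(receiver: str, neutral: str, sender: str, label: str) -> ProteinGene:
    return ProteinGene(
        BitDomain.from_string(receiver),
        BitDomain.from_string(neutral),
        BitDomain.from_string(sender),
        label,
    )


def random_host(rng, L=10) -> HostGenotype:
    return HostGenotype.from_array(rng.integers(0, 2, size=(5, 3, L), dtype=np.uint8))


def random_pathogen(rng, L=10) -> PathogenGenotype:
    return PathogenGenotype.from_array(
        rng.integers(0, 2, size=(3, L), dtype=np.uint8)
    )
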