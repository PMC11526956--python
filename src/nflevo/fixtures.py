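"""Hand-crafted genotypes for tests and demonstrations."""

from __future__ import annotations

import numpy as np

from .genotypes import SENDER, HostGenotype, PathogenGenotype

KINDS = ("aligned", "anti_aligned", "random", "near_threshold")


def make_fixture(
    kind: str, L: int, rng: np.random.Generator, offset: int = 0
) -> tuple[HostGenotype, PathogenGenotype]:
    """One (host, pathogen) genotype pair with known interaction structure.

    * ``aligned`` — every domain equals one shared random vector, so every
      potential interaction has mu = 1.
    * ``anti_aligned`` — all senders are the bitwise complement of all
      receivers: every interaction has mu = -1.
    * ``random`` — bits i.i.d. Bernoulli(0.5).
    * ``near_threshold`` — every sender sits at Hamming distance
      L/2 + ``offset`` from every receiver (offset in {-1, 0, 1});
      offset 0 gives mu = 0 exactly and requires even L.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
    host = np.empty((5, 3, L), dtype=np.uint8)
    pathogen = np.empty((3, L), dtype=np.uint8)
    if kind == "random":
        host[:] = rng.integers(0, 2, size=host.shape, dtype=np.uint8)
        pathogen[:] = rng.integers(0, 2, size=pathogen.shape, dtype=np.uint8)
    elif kind == "aligned":
        v = rng.integers(0, 2, size=L, dtype=np.uint8)
        host[:] = v
        pathogen[:] = v
    elif kind == "anti_aligned":
        v = rng.integers(0, 2, size=L, dtype=np.uint8)
        host[:] = v
        pathogen[:] = v
        host[:, SENDER, :] = 1 - v
        pathogen[SENDER, :] = 1 - v
    else:  # near_threshold
        if offset not in (-1, 0, 1):
            raise ValueError("near_threshold offset must be -1, 0 or 1")
        if L % 2 and offset == 0:
            raise ValueError("exact-half near_threshold fixture needs even L")
        flips = L // 2 + offset
        v = rng.integers(0, 2, size=L, dtype=np.uint8)
        sender = v.copy()
        sender[:flips] ^= 1
        host[:] = v
        pathogen[:] = v
        host[:, SENDER, :] = sender
        pathogen[SENDER, :] = sender
    return (
        HostGenotype.from_array(host),
        PathogenGenotype.from_array(pathogen),
    )
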