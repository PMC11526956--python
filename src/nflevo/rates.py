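"""Consensus-sequence divergence and the ka/ks (omega) rate estimator.

Every ``sample_interval`` generations the per-site 1-frequency of each
(protein, domain) is recorded.  The first sample is the *focal*
consensus FO; later samples are *temporal* consensuses TE.  Divergence
between the two is

    k = (1/L) * sum_l [ FO_l (1 - TE_l) + TE_l (1 - FO_l) ]

the per-site probability that a site changed state (1→0 plus 0→1
components).  Applied to the neutral domain this is ks, the neutral
benchmark; applied to the sender or receiver domain it is ka, and
omega = ka/ks measures selection: omega < 1 purifying, ≈ 1 neutral,
> 1 positive.

When the neutral domain saturates (ks above ``saturation_threshold``,
default 0.5) the focal consensus of *all three* domains of that protein
is reset to the current consensus — ka and ks always share a focal
epoch — and no omega is recorded for that sample.  omega is recorded
only while ks lies strictly inside (0, threshold); at ks = 0 the ratio
is undefined and stored as missing, never as ±inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import DOMAINS, HOST_PROTEINS, DimensionError

FUNCTIONAL_DOMAINS = ("receiver", "sender")


def divergence_k(FO: np.ndarray, TE: np.ndarray) -> float:
    """Per-site-normalized divergence between two consensus vectors."""
    FO = np.asarray(FO, dtype=float)
    TE = np.asarray(TE, dtype=float)
    if FO.shape != TE.shape or FO.ndim != 1:
        raise DimensionError("consensus vectors must be 1-D and equal length")
    return float(np.mean(FO * (1.0 - TE) + TE * (1.0 - FO)))


@dataclass
class ConsensusTrack:
    """Focal/temporal consensus state and the derived rate streams.

    ``records`` accumulates one row per (sample, protein, domain in
    receiver/sender) with columns sample_index, generation, protein,
    domain, ks, ka, omega, reset_flag; omega is NaN when not recorded.
    """

    proteins: Sequence[str] = HOST_PROTEINS
    sample_interval: int = 5
    saturation_threshold: float = 0.5
    FO: dict = field(default_factory=dict)  # (protein, domain) -> vector
    records: list = field(default_factory=list)
    n_samples: int = 0

    def update(self, consensus_by_domain: dict, generation: int) -> None:
        """Fold in one population sample.

        ``consensus_by_domain`` maps (protein, domain) to a length-L
        consensus vector for every tracked protein and all three domains.
        The first call initializes the focal consensus and records
        nothing.
        """
        if generation % self.sample_interval != 0:
            raise ValueError(
                f"generation {generation} is not a multiple of the "
                f"sample interval {self.sample_interval}"
            )
        if not self.FO:
            for p in self.proteins:
                for d in DOMAINS:
                    self.FO[(p, d)] = np.array(
                        consensus_by_domain[(p, d)], dtype=float
                    )
            self.n_samples += 1
            return

        idx = self.n_samples
        for p in self.proteins:
            ks = divergence_k(self.FO[(p, "neutral")], consensus_by_domain[(p, "neutral")])
            reset = ks > self.saturation_threshold
            record_omega = 0.0 < ks < self.saturation_threshold
            for d in FUNCTIONAL_DOMAINS:
                if record_omega:
                    ka = divergence_k(self.FO[(p, d)], consensus_by_domain[(p, d)])
                    omega = ka / ks
                else:
                    ka, omega = np.nan, np.nan
                self.records.append(
                    {
                        "sample_index": idx,
                        "generation": generation,
                        "protein": p,
                        "domain": d,
                        "ks": ks,
                        "ka": ka,
                        "omega": omega,
                        "reset_flag": bool(reset),
                    }
                )
            if reset:
                for d in DOMAINS:
                    self.FO[(p, d)] = np.array(
                        consensus_by_domain[(p, d)], dtype=float
                    )
        self.n_samples += 1

    def to_frame(self) -> pd.DataFrame:
        columns = [
            "sample_index", "generation", "protein", "domain",
            "ks", "ka", "omega", "reset_flag",
        ]
        return pd.DataFrame(self.records, columns=columns)


def update_track(track: ConsensusTrack, consensus_by_domain: dict, generation: int) -> ConsensusTrack:
    """Functional-style wrapper around :meth:`ConsensusTrack.update`."""
    track.update(consensus_by_domain, generation)
    return track


def summarize_omega(
    tracks: Sequence[ConsensusTrack | pd.DataFrame], protein: str, domain: str
) -> pd.DataFrame:
    """Pointwise mean and spread of omega across replicate runs.

    Replicates are aligned by sample index; missing omegas are skipped.
    Spread is the sample standard deviation (ddof=1; 0 for a single
    valid replicate).  Sample indices with no valid omega in any
    replicate are absent from the output.
    """
    if len(tracks) == 0:
        raise ValueError("at least one replicate track is required")
    frames = []
    for rep, t in enumerate(tracks):
        frame = t.to_frame() if isinstance(t, ConsensusTrack) else t
        sel = frame[(frame["protein"] == protein) & (frame["domain"] == domain)]
        sel = sel.dropna(subset=["omega"])
        frames.append(sel[["sample_index", "omega"]].assign(replicate=rep))
    pooled = pd.concat(frames, ignore_index=True)
    if pooled.empty:
        return pd.DataFrame(columns=["sample_index", "mean", "sd", "n"])
    grouped = pooled.groupby("sample_index")["omega"]
    out = grouped.agg(mean="mean", n="count")
    out["sd"] = grouped.std(ddof=1).fillna(0.0)
    return out.reset_index()[["sample_index", "mean", "sd", "n"]]
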