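"""Classify which signaling architecture evolved in a finished run.

Each potential interaction is called *activatory*, *inhibitory* or
*not_evolved* from the mean of its population-mean mu trajectory over
the final window of generations (default: last 10%, magnitude cutoff
0.25).  From the per-edge calls the architecture flags are derived:

* ``functional_pathway`` — R activates A and A activates I
* ``downstream_NFL_D`` — A activates D and D inhibits I (inhibition of
  the output reached in three signaling steps)
* ``downstream_NFL_A`` — D activates I while A inhibits I directly (the
  activator itself is the feedback loop; two steps to inhibition)
* ``upstream_NFL`` — A activates U and U inhibits R (feedback on input)

The pathogen-facing edges (R,P) and (P,I) typically oscillate under
host–pathogen coevolution, so their window amplitude is reported
alongside the mean and a large-amplitude edge is labelled *coevolving*
rather than not_evolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evolution import PAIR_EDGES, edge_column
from .genotypes import EDGES

ACTIVATORY = "activatory"
INHIBITORY = "inhibitory"
NOT_EVOLVED = "not_evolved"
COEVOLVING = "coevolving"

DEFAULT_WINDOW_FRACTION = 0.1
DEFAULT_THRESHOLD = 0.25
#: window peak-to-trough swing above which a pathogen-facing edge is
#: reported as coevolving rather than not evolved
DEFAULT_AMPLITUDE = 0.5


def _window(values: np.ndarray, window_fraction: float) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("trajectory too short to classify (need >= 10 samples)")
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")
    w = max(1, int(np.ceil(window_fraction * values.size)))
    return values[-w:]


def call_edge(
    mu_trajectory: np.ndarray,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    threshold: float = DEFAULT_THRESHOLD,
) -> str:
    """Three-way call for one interaction from its mu time series."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    window = _window(mu_trajectory, window_fraction)
    if np.isnan(window).all():
        return NOT_EVOLVED
    mean = float(np.nanmean(window))
    if mean > threshold:
        return ACTIVATORY
    if mean < -threshold:
        return INHIBITORY
    return NOT_EVOLVED


@dataclass(frozen=True)
class ArchitectureCall:
    """Per-edge calls plus the derived feedback-architecture flags."""

    edge_calls: Mapping[tuple[str, str], str]
    window_stats: Mapping[tuple[str, str], dict]
    window: tuple[int, int]
    threshold: float

    @property
    def functional_pathway(self) -> bool:
        return (
            self.edge_calls[("A", "R")] == ACTIVATORY
            and self.edge_calls[("I", "A")] == ACTIVATORY
        )

    @property
    def downstream_NFL_D(self) -> bool:
        return (
            self.edge_calls[("D", "A")] == ACTIVATORY
            and self.edge_calls[("I", "D")] == INHIBITORY
        )

    @property
    def downstream_NFL_A(self) -> bool:
        return (
            self.edge_calls[("I", "D")] == ACTIVATORY
            and self.edge_calls[("I", "A")] == INHIBITORY
        )

    @property
    def upstream_NFL(self) -> bool:
        return (
            self.edge_calls[("U", "A")] == ACTIVATORY
            and self.edge_calls[("R", "U")] == INHIBITORY
        )

    @property
    def steps_to_inhibition(self) -> int | None:
        """Signaling steps needed to downregulate the output I."""
        if self.downstream_NFL_A:
            return 2
        if self.downstream_NFL_D:
            return 3
        return None

    @property
    def architecture(self) -> str:
        if self.downstream_NFL_A:
            return "activator_NFL"
        if self.downstream_NFL_D:
            return "downstream_NFL"
        if not self.functional_pathway:
            return "non_functional"
        return "no_downstream_NFL"

    def flags(self) -> dict:
        return {
            "functional_pathway": self.functional_pathway,
            "downstream_NFL_D": self.downstream_NFL_D,
            "downstream_NFL_A": self.downstream_NFL_A,
            "upstream_NFL": self.upstream_NFL,
        }

    def to_dict(self) -> dict:
        return {
            "edges": {f"{i}<-{j}": c for (i, j), c in self.edge_calls.items()},
            "window_stats": {
                f"{i}<-{j}": s for (i, j), s in self.window_stats.items()
            },
            "flags": self.flags(),
            "architecture": self.architecture,
            "steps_to_inhibition": self.steps_to_inhibition,
            "window": list(self.window),
            "threshold": self.threshold,
        }


def classify_run(
    records: pd.DataFrame,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    threshold: float = DEFAULT_THRESHOLD,
    amplitude: float = DEFAULT_AMPLITUDE,
) -> ArchitectureCall:
    """Architecture call from a run's per-generation record frame.

    ``records`` must carry one ``mu_<target>_<source>`` column per edge
    (as written by the evolution engine) indexed by generation.
    """
    edge_calls: dict[tuple[str, str], str] = {}
    stats: dict[tuple[str, str], dict] = {}
    n = len(records)
    w = max(1, int(np.ceil(window_fraction * n)))
    for edge in EDGES:
        traj = records[edge_column(edge)].to_numpy(dtype=float)
        window = _window(traj, window_fraction)
        call = call_edge(traj, window_fraction, threshold)
        valid = window[~np.isnan(window)]
        stat = {
            "mean": float(valid.mean()) if valid.size else float("nan"),
            "amplitude": float(valid.max() - valid.min()) if valid.size else float("nan"),
        }
        if edge in PAIR_EDGES and call == NOT_EVOLVED and stat["amplitude"] > amplitude:
            call = COEVOLVING
        edge_calls[edge] = call
        stats[edge] = stat
    gen_last = int(records["generation"].iloc[-1]) if n else 0
    gen_first = int(records["generation"].iloc[-w]) if n else 0
    return ArchitectureCall(edge_calls, stats, (gen_first, gen_last), threshold)


def tabulate_replicates(calls: Sequence[ArchitectureCall]) -> dict:
    """Counts of each flag and architecture label across replicates."""
    calls = list(calls)
    if not calls:
        raise ValueError("at least one architecture call required")
    flag_names = list(calls[0].flags())
    counts = {name: sum(c.flags()[name] for c in calls) for name in flag_names}
    architectures: dict[str, int] = {}
    for c in calls:
        architectures[c.architecture] = architectures.get(c.architecture, 0) + 1
    return {"n": len(calls), "flags": counts, "architectures": architectures}
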