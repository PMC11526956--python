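"""Plain-text I/O: population snapshots, record/omega tables, metadata.

Snapshot format (tab-separated, one individual per line)::

    L=10    proteins=R,A,I,U,D
    0101...|11010...|00111...    ...   (one field per protein)

Each field holds the three domains of one protein in the order
receiver|neutral|sender, bits written left to right from site 1.
Pathogen snapshots use ``proteins=P``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import HOST_PROTEINS, HostPopulation, PathogenPopulation


def _format_individual(bits: np.ndarray) -> str:
    # bits: (n_proteins, 3, L)
    return "\t".join(
        "|".join("".join(str(int(b)) for b in domain) for domain in protein)
        for protein in bits
    )


def save_population(path, population) -> None:
    path = Path(path)
    if isinstance(population, HostPopulation):
        labels, bits = ",".join(HOST_PROTEINS), population.bits
    elif isinstance(population, PathogenPopulation):
        labels, bits = "P", population.bits[:, None, :, :]
    else:
        raise TypeError(f"cannot save {type(population).__name__}")
    lines = [f"L={population.L}\tproteins={labels}"]
    lines.extend(_format_individual(ind) for ind in bits)
    path.write_text("\n".join(lines) + "\n")


def load_population(path):
    path = Path(path)
    lines = path.read_text().splitlines()
    header = dict(part.split("=") for part in lines[0].split("\t"))
    L = int(header["L"])
    labels = header["proteins"].split(",")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        proteins = []
        for f in line.split("\t"):
            domains = f.split("|")
            if len(domains) != 3 or any(len(d) != L for d in domains):
                raise ValueError(f"malformed snapshot line in {path}")
            proteins.append(
                [[int(c) for c in domain] for domain in domains]
            )
        rows.append(proteins)
    bits = np.array(rows, dtype=np.uint8)
    if labels == ["P"]:
        return PathogenPopulation(bits[:, 0])
    if labels != list(HOST_PROTEINS):
        raise ValueError(f"unexpected protein labels {labels} in {path}")
    return HostPopulation(bits)


_FLOAT_FORMAT = "%.10g"


def write_table(path, frame: pd.DataFrame) -> None:
    """Deterministic TSV output (fixed float format, no index)."""
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def write_json(path, data: dict) -> None:
    Path(path).write_text(json.dumps(data, sort_keys=True, indent=2) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
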