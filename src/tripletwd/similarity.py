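"""Weight deviation: a weighted-L1 distance on triplet profiles.

For two sequences A and B with triplet-repeat model sets {<T_i, X_i>} and
{<T_i, Y_i>},

    WD(A, B) = ( sum_{i=1..64} |X_i - Y_i| * Psi(T_i) ) / 64.

Smaller values mean more similar sequences.  Counts are absolute, not
frequencies, so sequences of different length accrue length-driven
deviation by design.  Because the weights are tenths of integers and the
counts integers, the sum is computed in exact integer arithmetic and
divided once by 640 at the end; the only rounding is the final binary
float, well below display precision.

WD is a metric on profile space (a weighted L1 norm of the count
difference, scaled by 1/64): identity, symmetry and the triangle
inequality all hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .profiles import TripletProfile, profile_of_record
from .sequences import SequenceRecord
from .weights import WeightTable

__all__ = [
    "DistanceMatrix",
    "weight_deviation",
    "pairwise_matrix",
    "write_matrix",
    "read_matrix",
    "format_wd",
]


def weight_deviation(a: TripletProfile, b: TripletProfile, table: WeightTable) -> float:
    """The weight deviation between two profiles (exact to the last bit)."""
    if a.counts.shape != b.counts.shape:
        raise ValueError("profiles must both be 64-vectors in canonical order")
    tenths = np.array([table.tenths[t] for t in table.canonical_order], dtype=np.int64)
    total = int(np.abs(a.counts - b.counts) @ tenths)
    return total / 640.0


def format_wd(value: float, decimals: int = 4) -> str:
    """Format a WD value with half-up rounding (display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric nonnegative matrix of pairwise WD values."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("matrix labels must be unique")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(values).any():
            raise ValueError("distance matrix must have a zero diagonal")
        if (values < 0).any():
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", values)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def pairs(self) -> list[tuple[str, str, float]]:
        """Upper-triangle entries as (label_i, label_j, value), input order."""
        out = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                out.append((self.labels[i], self.labels[j], float(self.values[i, j])))
        return out


def pairwise_matrix(records: Sequence[SequenceRecord], table: WeightTable) -> DistanceMatrix:
    """All-against-all WD matrix over ``records`` (ids must be unique)."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for a pairwise matrix")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")
    profiles = [profile_of_record(r, table) for r in records]
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = weight_deviation(profiles[i], profiles[j], table)
    return DistanceMatrix(labels=tuple(ids), values=values)


def write_matrix(m: DistanceMatrix, destination, format: str = "csv") -> None:
    """Write a distance matrix as ``csv``, ``phylip`` or ``upper-triangle``.

    csv: full square matrix with label header row and column, 4-decimal
    half-up formatting.  phylip: standard square PHYLIP distance matrix.
    upper-triangle: labels across the top, each row starting at the
    diagonal — the layout similarity tables are conventionally printed in.
    """
    if format == "csv":
        lines = ["," + ",".join(m.labels)]
        for i, lab in enumerate(m.labels):
            lines.append(lab + "," + ",".join(format_wd(v) for v in m.values[i]))
    elif format == "phylip":
        lines = [f"{len(m.labels)}"]
        for i, lab in enumerate(m.labels):
            lines.append(f"{lab:<12}" + "  ".join(format_wd(v) for v in m.values[i]))
    elif format in ("upper-triangle", "triangle"):
        lines = ["\t" + "\t".join(m.labels)]
        for i, lab in enumerate(m.labels):
            cells = [""] * i + [format_wd(v) for v in m.values[i, i:]]
            lines.append(lab + "\t" + "\t".join(cells))
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
        return
    try:
        with open(destination, "w") as fh:
            fh.write(text)
    except OSError as exc:
        raise OSError(f"cannot write matrix to {destination}: {exc}") from exc


def read_matrix(source) -> DistanceMatrix:
    """Read a matrix written by :func:`write_matrix` (csv or phylip)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    first = lines[0]
    if "," in first:
        labels = tuple(first.split(",")[1:])
        rows = [[float(x) for x in ln.split(",")[1:]] for ln in lines[1:]]
    else:
        n = int(first.split()[0])
        labels_list = []
        rows = []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels_list.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        labels = tuple(labels_list)
    return DistanceMatrix(labels=labels, values=np.array(rows))
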