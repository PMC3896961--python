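"""Sequence handling and the 2D plot-set representation.

A coding sequence G = g1 g2 ... gN is read in frame 0 as consecutive
non-overlapping triplets t1 ... tM with M = floor(N/3) (a trailing partial
codon is dropped).  Mapping each triplet through the weight table turns the
sequence into the plot set

    Theta(G) = {(1, Psi(t1)), (2, Psi(t2)), ..., (M, Psi(tM))},

an alignment-free 2D graphical representation: position index on the x
axis, triplet weight on the y axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from .weights import InvalidTripletError, Triplet, WeightTable, _NUCLEOTIDES

__all__ = [
    "SequenceRecord",
    "PlotSet",
    "SequenceError",
    "clean_sequence",
    "to_triplets",
    "to_plot_set",
    "write_plot_set",
    "read_plot_set",
    "render_plot",
    "read_fasta",
    "write_fasta",
]

logger = logging.getLogger(__name__)


class SequenceError(ValueError):
    """Raised for sequences that fail strict validation."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identifier plus a nucleotide string (canonical uppercase A/C/G/T)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence record id must be non-empty")


def clean_sequence(raw: str, strict: bool = True) -> str:
    """Normalize ``raw`` to a canonical nucleotide string.

    Uppercases, transliterates U to T, and strips whitespace and digits
    (so numbered sequence listings paste in unchanged).  In strict mode any
    remaining non-ACGT character is an error reporting the character and its
    1-based position in the cleaned string; in permissive mode such
    characters are kept (downstream triplet counting excludes the triplets
    containing them).
    """
    cleaned = []
    for ch in raw:
        if ch.isspace() or ch.isdigit():
            continue
        ch = ch.upper()
        cleaned.append("T" if ch == "U" else ch)
    seq = "".join(cleaned)
    if strict:
        for pos, ch in enumerate(seq, start=1):
            if ch not in _NUCLEOTIDES:
                raise SequenceError(
                    f"non-nucleotide character {ch!r} at position {pos}"
                )
    return seq


def to_triplets(seq: str, skip_invalid: bool = False) -> list[Triplet]:
    """Split a cleaned sequence into frame-0 non-overlapping triplets.

    Returns floor(N/3) triplets; 1-2 trailing nucleotides are dropped (and
    logged).  With ``skip_invalid`` triplets containing a non-ACGT character
    are excluded instead of propagating an error later.
    """
    m = len(seq) // 3
    dropped = len(seq) - 3 * m
    if dropped:
        logger.info("dropped %d trailing nucleotide(s) of a partial codon", dropped)
    triplets = [seq[3 * i : 3 * i + 3] for i in range(m)]
    if skip_invalid:
        kept = [t for t in triplets if set(t) <= _NUCLEOTIDES]
        if len(kept) != len(triplets):
            logger.info("excluded %d triplet(s) with ambiguous characters", len(triplets) - len(kept))
        return kept
    return triplets


@dataclass(frozen=True)
class PlotSet:
    """Ordered (index, weight) pairs encoding one sequence; indices 1..M."""

    points: tuple[tuple[int, float], ...]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.points)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(p[0] for p in self.points)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.points)


def to_plot_set(record: SequenceRecord, table: WeightTable, skip_invalid: bool = False) -> PlotSet:
    """Map a record to its 2D plot set: point i is (i, Psi(t_i)), 1-based."""
    triplets = to_triplets(record.sequence, skip_invalid=skip_invalid)
    points = tuple((i, table.weight_of(t)) for i, t in enumerate(triplets, start=1))
    return PlotSet(points=points, source_id=record.id)


def write_plot_set(ps: PlotSet, destination) -> None:
    """Serialize a plot set as two-column TSV with an ``index\tweight`` header."""
    lines = ["index\tweight"]
    lines += [f"{i}\t{w:.1f}" for i, w in ps.points]
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
        return
    try:
        with open(destination, "w") as fh:
            fh.write(text)
    except OSError as exc:
        raise OSError(f"cannot write plot set to {destination}: {exc}") from exc


def read_plot_set(source, source_id: str = "") -> PlotSet:
    """Inverse of :func:`write_plot_set`."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    points = []
    for ln in lines[1:]:
        idx, weight = ln.split("\t")
        points.append((int(idx), float(weight)))
    return PlotSet(points=tuple(points), source_id=source_id)


def render_plot(ps: PlotSet, destination, title: str = "", style: str = "line") -> None:
    """Render the plot set to an image file (index vs weight).

    ``style`` is ``"line"`` (points joined, the conventional look for these
    graphical representations) or ``"scatter"``.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    if ps.points:
        if style == "scatter":
            ax.scatter(ps.indices, ps.weights, s=6)
        else:
            ax.plot(ps.indices, ps.weights, lw=0.8, marker=".", ms=3)
    ax.set_xlabel("triplet index")
    ax.set_ylabel("weight")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    try:
        fig.savefig(destination)
    finally:
        plt.close(fig)


def read_fasta(path, strict: bool = True) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into cleaned sequence records.

    The record id is the header up to the first whitespace; sequences are
    cleaned with :func:`clean_sequence`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = clean_sequence(str(rec.seq), strict=strict)
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], destination, width: int = 70) -> None:
    """Write records as FASTA with fixed line width."""
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i : i + width])
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w") as fh:
            fh.write(text)
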