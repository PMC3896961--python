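"""Canonical triplet weight table.

Every one of the 64 DNA triplets (the DNA counterparts of the mRNA codons,
U transliterated to T) carries a real-valued *weight*.  The integer part of
a weight indexes the amino-acid group the triplet codes for (alanine = 1,
arginine = 2, ..., methionine = 20, the three stop triplets = 21); the
fractional part distinguishes synonymous triplets within a group.  The
table is constructed so that any two synonymous triplets are closer in
weight than any two triplets coding different amino acids, which makes the
weight a faithful 1D embedding of the genetic code's degeneracy structure.

The weights are a fixed published constant, not a computed quantity.  They
are stored internally in tenths (scaled integers) so that all arithmetic on
them — in particular the weight-deviation distance — is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable

__all__ = [
    "Triplet",
    "AminoAcidGroup",
    "WeightTable",
    "OrderingReport",
    "build_weight_table",
    "validate_triplet",
    "verify_ordering_rule",
]

Triplet = str

_NUCLEOTIDES = frozenset("ACGT")


class InvalidTripletError(ValueError):
    """Raised when a string is not a valid A/C/G/T triplet."""


#: amino-acid groups in integer-part order; triplet order within a group
#: follows the fractional parts of the weight table below.
_GROUPS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("alanine", ("GCT", "GCC", "GCA", "GCG")),
    ("arginine", ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG")),
    ("aspartic acid", ("GAT", "GAC")),
    ("asparagine", ("AAT", "AAC")),
    ("cysteine", ("TGT", "TGC")),
    ("glutamic acid", ("GAA", "GAG")),
    ("glutamine", ("CAA", "CAG")),
    ("glycine", ("GGT", "GGC", "GGA", "GGG")),
    ("histidine", ("CAT", "CAC")),
    ("isoleucine", ("ATT", "ATC", "ATA")),
    ("leucine", ("CTT", "CTC", "CTA", "CTG", "TTA", "TTG")),
    ("lysine", ("AAA", "AAG")),
    ("phenylalanine", ("TTT", "TTC")),
    ("proline", ("CCT", "CCC", "CCA", "CCG")),
    ("serine", ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC")),
    ("threonine", ("ACT", "ACC", "ACA", "ACG")),
    ("tryptophan", ("TGG",)),
    ("tyrosine", ("TAT", "TAC")),
    ("valine", ("GTT", "GTC", "GTA", "GTG")),
    ("methionine", ("ATG",)),
    ("stop", ("TAA", "TAG", "TGA")),
)

#: triplet -> weight in tenths.  Transcribed verbatim from the published
#: table; several groups start their fractional part above .1 (aspartic
#: acid at .3, lysine at .3, threonine at .3, tryptophan at .3), an
#: irregularity of the published constant that is preserved, not smoothed.
_WEIGHT_TENTHS: dict[str, int] = {
    "GCT": 11, "GCC": 12, "GCA": 13, "GCG": 14,
    "CGT": 21, "CGC": 22, "CGA": 23, "CGG": 24, "AGA": 25, "AGG": 26,
    "GAT": 33, "GAC": 34,
    "AAT": 41, "AAC": 42,
    "TGT": 51, "TGC": 52,
    "GAA": 61, "GAG": 62,
    "CAA": 71, "CAG": 72,
    "GGT": 81, "GGC": 82, "GGA": 83, "GGG": 84,
    "CAT": 91, "CAC": 92,
    "ATT": 101, "ATC": 102, "ATA": 103,
    "CTT": 111, "CTC": 112, "CTA": 113, "CTG": 114, "TTA": 115, "TTG": 116,
    "AAA": 123, "AAG": 124,
    "TTT": 131, "TTC": 132,
    "CCT": 141, "CCC": 142, "CCA": 143, "CCG": 144,
    "TCT": 151, "TCC": 152, "TCA": 153, "TCG": 154, "AGT": 155, "AGC": 156,
    "ACT": 163, "ACC": 164, "ACA": 165, "ACG": 166,
    "TGG": 173,
    "TAT": 181, "TAC": 182,
    "GTT": 191, "GTC": 192, "GTA": 193, "GTG": 194,
    "ATG": 201,
    "TAA": 211, "TAG": 212, "TGA": 213,
}


def validate_triplet(s: str) -> Triplet:
    """Return the canonical uppercase DNA form of ``s`` (U -> T).

    Raises :class:`InvalidTripletError` naming the offending string if the
    input is not three characters over {A, C, G, T, U, u, ...}.
    """
    if not isinstance(s, str):
        raise InvalidTripletError(f"triplet must be a string, got {type(s).__name__}")
    t = s.upper().replace("U", "T")
    if len(t) != 3:
        raise InvalidTripletError(f"triplet {s!r} has length {len(t)}, expected 3")
    bad = [c for c in t if c not in _NUCLEOTIDES]
    if bad:
        raise InvalidTripletError(f"triplet {s!r} contains non-nucleotide character {bad[0]!r}")
    return t


@dataclass(frozen=True)
class AminoAcidGroup:
    """One amino acid (or the stop signal) with its synonymous triplets."""

    name: str
    triplets: tuple[Triplet, ...]
    integer_part: int


@dataclass(frozen=True)
class WeightTable:
    """The complete 64-entry triplet -> weight mapping.

    ``canonical_order`` is the fixed enumeration of the 64 triplets used to
    index triplet-count profiles; it walks the amino-acid groups in
    integer-part order, synonymous triplets in fractional-part order, from
    GCT (alanine, weight 1.1) to TGA (stop, weight 21.3).
    """

    groups: tuple[AminoAcidGroup, ...]
    canonical_order: tuple[Triplet, ...]
    tenths: dict[Triplet, int]

    @property
    def entries(self) -> dict[Triplet, float]:
        """Triplet -> weight as decimal numbers."""
        return {t: v / 10.0 for t, v in self.tenths.items()}

    def weight_of(self, t: str) -> float:
        """The weight of triplet ``t`` (RNA codons accepted via U -> T)."""
        return self.weight_tenths(t) / 10.0

    def weight_tenths(self, t: str) -> int:
        """The weight of ``t`` scaled by 10, as an exact integer."""
        return self.tenths[validate_triplet(t)]

    def amino_acid_of(self, t: str) -> str:
        """The amino-acid name (or ``"stop"``) whose group contains ``t``."""
        return self.groups[self.tenths[validate_triplet(t)] // 10 - 1].name

    def index_of(self, t: str) -> int:
        """Position of ``t`` in the canonical 64-triplet order (0-based)."""
        return self.canonical_order.index(validate_triplet(t))


@lru_cache(maxsize=1)
def build_weight_table() -> WeightTable:
    """Assemble the canonical weight table (a cached constant)."""
    groups = tuple(
        AminoAcidGroup(name=name, triplets=triplets, integer_part=i + 1)
        for i, (name, triplets) in enumerate(_GROUPS)
    )
    order = tuple(t for g in groups for t in g.triplets)
    table = WeightTable(groups=groups, canonical_order=order, tenths=dict(_WEIGHT_TENTHS))
    _check_table(table)
    return table


def _check_table(table: WeightTable) -> None:
    if len(table.tenths) != 64 or set(table.canonical_order) != set(table.tenths):
        raise AssertionError("weight table must cover exactly the 64 triplets")
    if len(set(table.tenths.values())) != 64 or min(table.tenths.values()) <= 0:
        raise AssertionError("weights must be distinct and positive")
    for g in table.groups:
        if any(table.tenths[t] // 10 != g.integer_part for t in g.triplets):
            raise AssertionError(f"group {g.name}: integer parts disagree with weights")


@dataclass(frozen=True)
class OrderingReport:
    """Result of the synonymy-ordering check on a weight table.

    ``max_within`` is the largest weight gap between two triplets coding the
    same amino acid, ``min_between`` the smallest gap between two triplets
    coding different amino acids (both in weight units); the rule holds when
    the former is strictly smaller than the latter.
    """

    max_within: float
    min_between: float
    passes: bool
    degenerate: bool = False


def verify_ordering_rule(table: WeightTable) -> OrderingReport:
    """Exhaustively check that same-group gaps stay below cross-group gaps.

    Enumerates all unordered pairs of triplets (2016 for the full table),
    partitions them by whether the two triplets are synonymous, and compares
    the extreme gaps.  A table with a single group has no cross-group pairs;
    the report then passes vacuously and is flagged degenerate.
    """
    group_of = {t: g.integer_part for g in table.groups for t in g.triplets}
    within: list[int] = []
    between: list[int] = []
    for a, b in combinations(table.tenths, 2):
        gap = abs(table.tenths[a] - table.tenths[b])
        (within if group_of[a] == group_of[b] else between).append(gap)
    if not between:
        return OrderingReport(
            max_within=max(within, default=0) / 10.0,
            min_between=float("inf"),
            passes=True,
            degenerate=True,
        )
    max_within = max(within, default=0)
    min_between = min(between)
    return OrderingReport(
        max_within=max_within / 10.0,
        min_between=min_between / 10.0,
        passes=max_within < min_between,
    )


def write_weight_table(table: WeightTable, destination) -> None:
    """Write the table as two-column TSV (triplet, weight) in canonical order."""
    lines = ["triplet\tweight"]
    lines += [f"{t}\t{table.tenths[t] / 10.0:.1f}" for t in table.canonical_order]
    _write_text(destination, "\n".join(lines) + "\n")


def _write_text(destination, text: str) -> None:
    if hasattr(destination, "write"):
        destination.write(text)
        return
    try:
        with open(destination, "w") as fh:
            fh.write(text)
    except OSError as exc:
        raise OSError(f"cannot write to {destination}: {exc}") from exc
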