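"""Triplet-occurrence profiles.

The *triplet-repeat model set* of a sequence is the 64-long vector of
occurrence counts delta(T_i) of each canonical triplet T_i among the
sequence's frame-0 triplets.  Profiles are aligned to the weight table's
canonical order (GCT first, TGA last), never alphabetical, so that
downstream weighted comparisons index the same triplet everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequences import SequenceRecord, clean_sequence, to_triplets
from .weights import Triplet, WeightTable, validate_triplet

__all__ = [
    "TripletProfile",
    "triplet_counts",
    "profile_of_record",
    "write_profiles",
    "read_profiles",
]


@dataclass(frozen=True)
class TripletProfile:
    """64-vector of nonnegative triplet counts in canonical order."""

    counts: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (64,):
            raise ValueError(f"profile must have 64 counts, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("profile counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def m(self) -> int:
        """Total number of triplets counted (floor(N/3) for strict input)."""
        return int(self.counts.sum())


def triplet_counts(
    triplets: Sequence[str], table: WeightTable, source_id: str = ""
) -> TripletProfile:
    """Count occurrences of each canonical triplet in ``triplets``.

    Triplets absent from the input get count 0; every input triplet is
    validated (RNA codons accepted via U -> T).
    """
    index = {t: i for i, t in enumerate(table.canonical_order)}
    counts = np.zeros(64, dtype=np.int64)
    for t in triplets:
        counts[index[validate_triplet(t)]] += 1
    return TripletProfile(counts=counts, source_id=source_id)


def profile_of_record(
    record: SequenceRecord, table: WeightTable, strict: bool = True
) -> TripletProfile:
    """Clean, split into frame-0 triplets, and count, in one step."""
    seq = clean_sequence(record.sequence, strict=strict)
    triplets = to_triplets(seq, skip_invalid=not strict)
    return triplet_counts(triplets, table, source_id=record.id)


def write_profiles(
    profiles: Iterable[TripletProfile], destination, table: WeightTable
) -> None:
    """Write profiles as TSV: one row per profile, id + 64 counts.

    The header names the triplets in canonical order, so the file is
    self-describing and diffable.
    """
    lines = ["id\t" + "\t".join(table.canonical_order)]
    for p in profiles:
        lines.append(p.source_id + "\t" + "\t".join(str(c) for c in p.counts))
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w") as fh:
            fh.write(text)


def read_profiles(source, table: WeightTable) -> list[TripletProfile]:
    """Inverse of :func:`write_profiles`; validates the header order."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if tuple(header[1:]) != table.canonical_order:
        raise ValueError("profile file header does not match canonical triplet order")
    out = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        out.append(
            TripletProfile(
                counts=np.array([int(x) for x in parts[1:]], dtype=np.int64),
                source_id=parts[0],
            )
        )
    return out
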