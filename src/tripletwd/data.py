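"""Bundled reference data and the seeded random-sequence generator.

The package ships the complete coding sequences of the beta-globin genes of
11 species — Human, Chimpanzee, Gorilla, Black lemur, Norway rat, House
mouse, Goat, Bovine, Rabbit, Opossum and Gallus — the classic benchmark set
for alignment-free DNA similarity measures, transcribed verbatim from the
published listing (identifiers use underscores for file-system safety).
The chimpanzee and gorilla entries are shorter than the human one (376 and
364 nt vs 444 nt); the measure is computed on absolute counts, so those
length differences contribute to the distances by design.

``PUBLISHED_WD`` holds the published pairwise weight-deviation values for
the same 11 sequences, bundled so a recomputation can be checked
entry-for-entry.  The recomputed matrix reproduces all published pairs
except the ten involving Gallus, which differ by a single GAT/AGG codon
count in the Gallus input (see the comparison report and the methods
notes); the sequences here remain as printed.
"""

from __future__ import annotations

import numpy as np

from .sequences import SequenceRecord, write_fasta
from .similarity import DistanceMatrix
from .weights import build_weight_table

__all__ = [
    "SPECIES",
    "BETA_GLOBIN_CDS",
    "PUBLISHED_WD",
    "load_beta_globin",
    "published_matrix",
    "random_cds",
    "export_fasta",
]

#: benchmark species in published matrix order
SPECIES: tuple[str, ...] = (
    "Human", "Chimpanzee", "Gorilla", "Black_lemur", "Norway_rat",
    "House_mouse", "Goat", "Bovine", "Rabbit", "Opossum", "Gallus",
)

BETA_GLOBIN_CDS: dict[str, str] = {
    "Human": (
        "ATGGTGCACCTGACTCCTGAGGAGAAGTCTGCCGTTACTGCCCTGTGGGGCAAGGTGAAC"
        "GTGGATGAAGTTGGTGGTGAGGCCCTGGGCAGGCTGCTGGTGGTCTACCCTTGGACCCAG"
        "AGGTTCTTTGAGTCCTTTGGGGATCTGTCCACTCCTGATGCTGTTATGGGCAACCCTAAG"
        "GTGAAGGCTCATGGCAAGAAAGTGCTCGGTGCCTTTAGTGATGGCCTGGCTCACCTGGAC"
        "AACCTCAAGGGCACCTTTGCCACACTGAGTGAGCTGCACTGTGACAAGCTGCACGTGGAT"
        "CCTGAGAACTTCAGGCTCCTGGGCAACGTGCTGGTCTGTGTGCTGGCCCATCACTTTGGC"
        "AAAGAATTCACCCCACCAGTGCAGGCTGCCTATCAGAAAGTGGTGGCTGGTGTGGCTAAT"
        "GCCCTGGCCCACAAGTATCACTAA"
    ),
    "Chimpanzee": (
        "ATGGTGCACCTGACTCCTGAGGAGAAGTCTGCCGTTACTGCCCTGTGGGGCAAGGTGAAC"
        "GTGGATGAAGTTGGTGGTGAGGCCCTGGGCAGGTTGGTATCAAGGCTGCTGGTGGTCTAC"
        "CCTTGGACCCAGAGGTTCTTTGAGTCCTTTGGGGATCTGTCCACTCCTGATGCTGTTATG"
        "GGCAACCCTAAGGTGAAGGCTCATGGCAAGAAAGTGCTCGGTGCCTTTAGTGATGGCCTG"
        "GCTCACCTGGACAACCTCAAGGGCACCTTTGCCACACTGAGTGAGCTGCACTGTGACAAG"
        "CTGCACGTGGATCCTGAGAACTTCAGGCTCCTGGGCAACGTGCTGGTCTGTGTGCTGGCC"
        "CATCACTTTGGCAAAG"
    ),
    "Gorilla": (
        "ATGGTGCACCTGACTCCTGAGGAGAAGTCTGCCGTTACTGCCCTGTGGGGCAAGGTGAAC"
        "GTGGATGAAGTTGGTGGTGAGGCCCTGGGCAGGCTGCTGGTGGTCTACCCTTGGACCCAG"
        "AGGTTCTTTGAGTCCTTTGGGGATCTGTCCACTCCTGATGCTGTTATGGGCAACCCTAAG"
        "GTGAAGGCTCATGGCAAGAAAGTGCTCGGTGCCTTTAGTGATGGCCTGGCTCACCTGGAC"
        "AACCTCAAGGGCACCTTTGCCACACTGAGTGAGCTGCACTGTGACAAGCTGCACGTGGAT"
        "CCTGAGAACTTCAAGCTCCTGGGCAATGTGCTGGTCTGTGTGCTGGCCCATCACTTTGGC"
        "AAAG"
    ),
    "Black_lemur": (
        "ATGACTTTGCTGAGTGCTGAGGAGAATGCTCATGTCACCTCTCTGTGGGGCAAGGTGGAT"
        "GTAGAGAAAGTTGGTGGCGAGGCCTTGGGCAGGCTGCTGGTCGTCTACCCATGGACCCAG"
        "AGGTTCTTCGAGTCCTTTGGGGACCTGTCCTCTCCTTCTGCTGTTATGGGGAACCCTAAG"
        "GTGAAGGCCCATGGCAAGAAGGTGCTGAGTGCCTTTAGTGAAGGTCTGCATCACCTGGAC"
        "AACCTCAAGGGCACCTTTGCTCAACTGAGTGAGCTGCACTGTGACAAGTTGCACGTGGAT"
        "CCTCAGAACTTCACTCTCCTGGGCAACGTGCTGGTGGTTGTGCTGGCTGAACACTTTGGC"
        "AATGCATTCAGCCCGGCGGTGCAGGCTGCCTTTCAGAAGGTGGTGGCTGGTGTGGCCAAT"
        "GCTCTGGCTCACAAGTACCACTGA"
    ),
    "Norway_rat": (
        "ATGGTGCACCTAACTGATGCTGAGAAGGCTACTGTTAGTGGCCTGTGGGGAAAGGTGAAT"
        "GCTGATAATGTTGGCGCTGAGGCCCTGGGCAGGCTGCTGGTTGTCTACCCTTGGACCCAG"
        "AGGTACTTTTCTAAATTTGGGGACCTGTCCTCTGCCTCTGCTATCATGGGTAACCCCCAG"
        "GTGAAGGCCCATGGCAAGAAGGTGATAAATGCCTTCAATGATGGCCTGAAACACTTGGAC"
        "AACCTCAAGGGCACCTTTGCTCATCTGAGTGAACTCCACTGTGACAAGCTGCATGTGGAT"
        "CCTGAGAACTTCAGGCTCCTGGGCAATATGATTGTGATTGTGTTGGGCCACCACCTGGGC"
        "AAGGAATTCACCCCCTGTGCACAGGCTGCCTTCCAGAAGGTGGTGGCTGGAGTGGCCAGT"
        "GCCCTGGCTCACAAGTACCACTAA"
    ),
    "House_mouse": (
        "ATGGTGCACCTGACTGATGCTGAGAAGTCTGCTGTCTCTTGCCTGTGGGCAAAGGTGAAC"
        "CCCGATGAAGTTGGTGGTGAGGCCCTGGGCAGGCTGCTGGTTGTCTACCCTTGGACCCAG"
        "CGGTACTTTGATAGCTTTGGAGACCTATCCTCTGCCTCTGCTATCATGGGTAATCCCAAG"
        "GTGAAGGCCCATGGCAAAAAGGTGATAACTGCCTTTAACGAGGGCCTGAAAAACCTGGAC"
        "AACCTCAAGGGCACCTTTGCCAGCCTCAGTGAGCTCCACTGTGACAAGCTGCATGTGGAT"
        "CCTGAGAACTTCAGGCTCCTAGGCAATGCGATCGTGATTGTGCTGGGCCACCACCTGGGC"
        "AAGGATTTCACCCCTGCTGCACAGGCTGCCTTCCAGAAGGTGGTGGCTGGAGTGGCCACT"
        "GCCCTGGCTCACAAGTACCACTAA"
    ),
    "Goat": (
        "ATGCTGACTGCTGAGGAGAAGGCTGCCGTCACCGGCTTCTGGGGCAAGGTGAAAGTGGAT"
        "GAAGTTGGTGCTGAGGCCCTGGGCAGGCTGCTGGTTGTCTACCCCTGGACTCAGAGGTTC"
        "TTTGAGCACTTTGGGGACTTGTCCTCTGCTGATGCTGTTATGAACAATGCTAAGGTGAAG"
        "GCCCATGGCAAGAAGGTGCTAGACTCCTTTAGTAACGGCATGAAGCATCTTGACGACCTC"
        "AAGGGCACCTTTGCTCAGCTGAGTGAGCTGCACTGTGATAAGCTGCACGTGGATCCTGAG"
        "AACTTCAAGCTCCTGGGCAACGTGCTGGTGGTTGTGCTGGCTCGCCACCATGGCAGTGAA"
        "TTCACCCCGCTGCTGCAGGCTGAGTTTCAGAAGGTGGTGGCTGGTGTTGCCAATGCCCTG"
        "GCCCACAGATATCACTAA"
    ),
    "Bovine": (
        "ATGCTGACTGCTGAGGAGAAGGCTGCCGTCACCGCCTTTTGGGGCAAGGTGAAAGTGGAT"
        "GAAGTTGGTGGTGAGGCCCTGGGCAGGCTGCTGGTTGTCTACCCCTGGACTCAGAGGTTC"
        "TTTGAGTCCTTTGGGGACTTGTCCACTGCTGATGCTGTTATGAACAACCCTAAGGTGAAG"
        "GCCCATGGCAAGAAGGTGCTAGATTCCTTTAGTAATGGCATGAAGCATCTCGATGACCTC"
        "AAGGGCACCTTTGCTGCGCTGAGTGAGCTGCACTGTGATAAGCTGCATGTGGATCCTGAG"
        "AACTTCAAGCTCCTGGGCAACGTGCTAGTGGTTGTGCTGGCTCGCAATTTTGGCAAGGAA"
        "TTCACCCCGGTGCTGCAGGCTGACTTTCAGAAGGTGGTGGCTGGTGTGGCCAATGCCCTG"
        "GCCCACAGATATCATTAA"
    ),
    "Rabbit": (
        "ATGGTGCATCTGTCCAGTGAGGAGAAGTCTGCGGTCACTGCCCTGTGGGGCAAGGTGAAT"
        "GTGGAAGAAGTTGGTGGTGAGGCCCTGGGCAGGCTGCTGGTTGTCTACCCATGGACCCAG"
        "AGGTTCTTCGAGTCCTTTGGGGACCTGTCCTCTGCAAATGCTGTTATGAACAATCCTAAG"
        "GTGAAGGCTCATGGCAAGAAGGTGCTGGCTGCCTTCAGTGAGGGTCTGAGTCACCTGGAC"
        "AACCTCAAAGGCACCTTTGCTAAGCTGAGTGAACTGCACTGTGACAAGCTGCACGTGGAT"
        "CCTGAGAACTTCAGGCTCCTGGGCAACGTGCTGGTTATTGTGCTGTCTCATCATTTTGGC"
        "AAAGAATTCACTCCTCAGGTGCAGGCTGCCTATCAGAAGGTGGTGGCTGGTGTGGCCAAT"
        "GCCCTGGCTCACAAATACCACTGA"
    ),
    "Opossum": (
        "ATGGTGCACTTGACTTCTGAGGAGAAGAACTGCATCACTACCATCTGGTCTAAGGTGCAG"
        "GTTGACCAGACTGGTGGTGAGGCCCTTGGCAGGATGCTCGTTGTCTACCCCTGGACCACC"
        "AGGTTTTTTGGGAGCTTTGGTGATCTGTCCTCTCCTGGCGCTGTCATGTCAAATTCTAAG"
        "GTTCAAGCCCATGGTGCTAAGGTGTTGACCTCCTTCGGTGAAGCAGTCAAGCATTTGGAC"
        "AACCTGAAGGGTACTTATGCCAAGTTGAGTGAGCTCCACTGTGACAAGCTGCATGTGGAC"
        "CCTGAGAACTTCAAGATGCTGGGGAATATCATTGTGATCTGCCTGGCTGAGCACTTTGGC"
        "AAGGATTTTACTCCTGAATGTCAGGTTGCTTGGCAGAAGCTCGTGGCTGGAGTTGCCCAT"
        "GCCCTGGCCCACAAGTACCACTAA"
    ),
    "Gallus": (
        "ATGGTGCACTGGACTGCTGAGGAGAAGCAGCTCATCACCGGCCTCTGGGGCAAGGTCAAT"
        "GTGGCCGAATGTGGGGCCGAAGCCCTGGCCAGGCTGCTGATCGTCTACCCCTGGACCCAG"
        "AGGTTCTTTGCGTCCTTTGGGAACCTCTCCAGCCCCACTGCCATCCTTGGCAACCCCATG"
        "GTCCGCGCCCACGGCAAGAAAGTGCTCACCTCCTTTGGGGATGCTGTGAAGAACCTGGAC"
        "AACATCAAGAACACCTTCTCCCAACTGTCCGAACTGCATTGTGACAAGCTGCATGTGGAC"
        "CCCGAGAACTTCAGGCTCCTGGGTGACATCCTCATCATTGTCCTGGCCGCCCACTTCAGC"
        "AAGGACTTCACTCCTGAATGCCAGGCTGCCTGGCAGAAGCTGGTCCGCGTGGTGGCCCAT"
        "GCCCTGGCTCGCAAGTACCACTAA"
    ),
}

#: published pairwise weight-deviation values (upper triangle)
PUBLISHED_WD: dict[tuple[str, str], float] = {
    ("Human", "Chimpanzee"): 5.2500,
    ("Human", "Gorilla"): 4.3359,
    ("Human", "Black_lemur"): 8.5891,
    ("Human", "Norway_rat"): 10.670,
    ("Human", "House_mouse"): 9.7047,
    ("Human", "Goat"): 8.2219,
    ("Human", "Bovine"): 8.1438,
    ("Human", "Rabbit"): 7.8281,
    ("Human", "Opossum"): 15.6078,
    ("Human", "Gallus"): 16.7109,
    ("Chimpanzee", "Gorilla"): 1.1266,
    ("Chimpanzee", "Black_lemur"): 8.0297,
    ("Chimpanzee", "Norway_rat"): 10.645,
    ("Chimpanzee", "House_mouse"): 9.6016,
    ("Chimpanzee", "Goat"): 8.4375,
    ("Chimpanzee", "Bovine"): 9.3219,
    ("Chimpanzee", "Rabbit"): 9.6000,
    ("Chimpanzee", "Opossum"): 14.2578,
    ("Chimpanzee", "Gallus"): 15.8734,
    ("Gorilla", "Black_lemur"): 7.8688,
    ("Gorilla", "Norway_rat"): 9.9625,
    ("Gorilla", "House_mouse"): 8.6063,
    ("Gorilla", "Goat"): 7.6734,
    ("Gorilla", "Bovine"): 8.5578,
    ("Gorilla", "Rabbit"): 8.5547,
    ("Gorilla", "Opossum"): 13.9719,
    ("Gorilla", "Gallus"): 14.8781,
    ("Black_lemur", "Norway_rat"): 8.7219,
    ("Black_lemur", "House_mouse"): 9.5500,
    ("Black_lemur", "Goat"): 7.1328,
    ("Black_lemur", "Bovine"): 9.3891,
    ("Black_lemur", "Rabbit"): 5.6891,
    ("Black_lemur", "Opossum"): 12.9281,
    ("Black_lemur", "Gallus"): 15.2000,
    ("Norway_rat", "House_mouse"): 6.0750,
    ("Norway_rat", "Goat"): 7.0484,
    ("Norway_rat", "Bovine"): 9.3641,
    ("Norway_rat", "Rabbit"): 9.6578,
    ("Norway_rat", "Opossum"): 13.5906,
    ("Norway_rat", "Gallus"): 14.1219,
    ("House_mouse", "Goat"): 9.4953,
    ("House_mouse", "Bovine"): 9.2641,
    ("House_mouse", "Rabbit"): 10.7984,
    ("House_mouse", "Opossum"): 12.3406,
    ("House_mouse", "Gallus"): 12.3688,
    ("Goat", "Bovine"): 5.2625,
    ("Goat", "Rabbit"): 8.7219,
    ("Goat", "Opossum"): 11.9703,
    ("Goat", "Gallus"): 14.5359,
    ("Bovine", "Rabbit"): 9.2906,
    ("Bovine", "Opossum"): 12.5922,
    ("Bovine", "Gallus"): 15.0234,
    ("Rabbit", "Opossum"): 14.8984,
    ("Rabbit", "Gallus"): 15.6953,
    ("Opossum", "Gallus"): 14.2750,
}


def load_beta_globin() -> list[SequenceRecord]:
    """The 11 benchmark records, in published matrix order."""
    return [SequenceRecord(id=sid, sequence=BETA_GLOBIN_CDS[sid]) for sid in SPECIES]


def published_matrix() -> DistanceMatrix:
    """The published 11x11 weight-deviation matrix as a DistanceMatrix."""
    n = len(SPECIES)
    values = np.zeros((n, n))
    for (a, b), v in PUBLISHED_WD.items():
        i, j = SPECIES.index(a), SPECIES.index(b)
        values[i, j] = values[j, i] = v
    return DistanceMatrix(labels=SPECIES, values=values)


def random_cds(n_codons: int, seed: int, id: str | None = None) -> SequenceRecord:
    """A random coding-style sequence of ``3 * n_codons`` bases.

    Triplets are sampled uniformly over the 64 possibilities with a seeded
    generator, so the same seed always yields the same sequence.
    """
    if n_codons < 1:
        raise ValueError(f"n_codons must be >= 1, got {n_codons}")
    rng = np.random.default_rng(seed)
    order = build_weight_table().canonical_order
    seq = "".join(order[i] for i in rng.integers(0, 64, size=n_codons))
    return SequenceRecord(id=id or f"random_{seed}", sequence=seq)


def export_fasta(destination) -> None:
    """Write the 11 benchmark records as FASTA."""
    write_fasta(load_beta_globin(), destination)
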