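# Methods

## The weight table

The core constant is a mapping Ψ from the 64 DNA triplets to distinct
positive decimals.  Weights are structured as `integer.fraction`: the
integer part (1–21) indexes the amino-acid group in a fixed order
(alanine 1, arginine 2, …, methionine 20, stop 21) and the fractional part
enumerates synonymous triplets within the group.  The table is transcribed
verbatim as a literal constant rather than derived from the construction
rule, because the published table deviates from the rule in four groups:
aspartic acid starts at .3 (GAT = 3.3, not 3.1), as do lysine (AAA = 12.3),
threonine (ACT = 16.3) and tryptophan (TGG = 17.3).  The printed table is
the artifact the published results depend on, so those irregular fractional
parts are preserved, not smoothed; the recomputed benchmark confirms that
choice (see below).

Weights are stored internally in tenths (scaled integers).  Every weight
has exactly one decimal digit, so this representation is exact: equality
tests on weights are exact, and the weight deviation is computed in integer
arithmetic with a single division at the end.

The table's defining property — any two synonymous triplets are closer in
weight than any two non-synonymous ones — is verified by exhaustive
enumeration over all 2016 unordered triplet pairs: the maximum within-group
gap is 0.5 (six-fold degenerate groups such as leucine, 11.1–11.6) and the
minimum between-group gap is 0.7 (adjacent groups, e.g. GCG = 1.4 vs
CGT = 2.1).  `verify_ordering_rule` reports both extremes; a table with a
single group has no between-group pairs and is flagged degenerate (the
check passes vacuously).

RNA codons are accepted everywhere through U→T transliteration.

## Sequence handling

Sequences are read in frame 0 from the first base, matching the assumption
that inputs are complete coding sequences starting at ATG; there is no
frame search, ORF detection, or reverse-complement handling.  A trailing
partial codon (N mod 3 bases) is dropped per M = ⌊N/3⌋ and logged at info
level.  Cleaning uppercases, transliterates U→T, and strips whitespace and
digits so numbered sequence listings paste in unchanged.  Strict mode
(default) rejects any other character, naming it and its position;
permissive mode keeps such characters and the triplets containing them are
excluded from plot sets and counts.

Plot-set indices are 1-based, `(1, Ψ(t₁)) … (M, Ψ(t_M))`.  Rendering joins
points with a thin line plus markers by default (a scatter style is
available); the figure is a best-effort visual, and only the coordinates
are contractual.

## Weight deviation

WD(A, B) = Σ|Xᵢ−Yᵢ|·Ψ(Tᵢ)/64 is evaluated as sum-then-divide: with counts
and tenths-scaled weights both integers, the sum is an exact integer and
the only rounding is the final division by 640 into a binary double —
far below the 4-decimal display precision.  Division once at the end is
mathematically identical to per-term division and avoids accumulating
rounding steps.

Counts are absolute, not length-normalized frequencies: two sequences of
different length accrue deviation from the length difference itself, by
design of the measure.  WD is a weighted L1 metric on profile space —
identity, symmetry, triangle inequality, translation invariance (adding the
same triplet count to both profiles) and 1-homogeneity in the counts all
hold exactly and are property-tested.

Displayed values use 4-decimal half-up rounding, the dominant convention of
the published benchmark table; the one published value printed as 10.670
(human–rat) is treated as 5-significant-digit formatting of the same
quantity and compared at its printed precision.

## Profiles and serialization

Profile vectors are ordered by the canonical 64-triplet enumeration (GCT,
GCC, … TGA — amino-acid groups in integer-part order, synonymous triplets
in fractional-part order), never alphabetically, so serialized profiles and
the weighted comparison index the same triplet everywhere.  Profiles write
as a 65-column TSV (id + 64 counts) with the triplet names as header;
readers validate the header order.  Matrices write as full-square CSV,
square PHYLIP, or the upper-triangle layout similarity tables are
conventionally printed in.

## Tree building

The benchmark publication shows a tree but does not name the method, so
only clade-level claims are treated as reproducible and both standard
distance-matrix methods are offered; UPGMA is the default.  UPGMA uses
cluster-size-weighted average linkage with merge height d/2, giving an
ultrametric rooted tree; neighbor joining follows the Saitou–Nei update
and emits an unrooted tree with a trifurcating root.  Determinism: when two
candidate pairs tie on the merge criterion, the pair whose sorted label
pair is lexicographically smallest merges first, internal clusters being
labelled by their smallest leaf label.  Negative NJ branch-length estimates
(possible on non-additive inputs) are clamped to zero so emitted trees
always satisfy the nonnegative-length invariant.  Newick output uses
6-decimal branch lengths and single-quotes labels containing whitespace or
Newick punctuation.

On the recomputed benchmark matrix, the UPGMA tree merges gorilla with
chimpanzee first (height 0.5633), joins human to that pair, and only later
attaches any other species, so the three primates form a clade — the
testable grouping claim.  Opossum and *Gallus* attach last.

## The bundled benchmark and its known inconsistency

The 11 β-globin coding sequences ship verbatim from the published listing
(human 444 nt, chimpanzee 376 nt, gorilla 364 nt, goat/bovine 438 nt, the
rest 444 nt; ids use underscores, e.g. `Black_lemur`).  A checksum test
guards the constants against accidental edits.  The published pairwise
weight-deviation values are bundled alongside so a recomputation can be
compared entry-for-entry.

Recomputation reproduces 45 of the 55 published pairs to within 5×10⁻⁴
after rounding.  The ten exceptions are exactly the pairs involving
*Gallus*, with residuals of ±7/640 (human, chimpanzee, rat) or ±59/640
(all others).  Those two magnitudes identify the cause uniquely: 7 and 59
tenths are the difference and sum of the weights of GAT (3.3) and AGG
(2.6), so the published matrix must have been computed from a *Gallus*
input containing one more GAT and one fewer AGG than the published
*Gallus* sequence — a single-codon discrepancy in the source data, not a
property of the measure.  The published *Gallus* sequence has in-frame AGG
at codons 31, 41 and 105, each an arginine in the canonical *Gallus*
β-globin protein, which supports keeping the sequence as published.  The
`reproduce` pipeline therefore reports these ten residuals explicitly
rather than patching either the sequence or the expected values, and the
golden tests document them as known failures of the published data's
internal consistency.

## Synthetic data

`random_cds(n_codons, seed)` samples triplets uniformly over the 64
possibilities with a seeded generator.  It emulates only the structural
features the algorithms consume — in-frame triplet composition of a given
length, deterministic per seed — and none of the biology of real coding
sequences (no start/stop structure, no codon-usage bias, no base-composition
skew, no homology between draws).  Property tests built on it therefore
establish algorithmic correctness (counting, metric axioms, tree
invariants), not biological performance of the measure; the biological
surface is exercised by the bundled benchmark instead.  Uniformity is
itself tested: over 10,000 codons each triplet's empirical frequency lies
within three binomial standard errors of 1/64.

## Problem sizes and tolerances

The bundled benchmark (11 sequences, ≤ 444 nt) runs in well under a second;
property suites use 500 random profile triples, 200 random sequences of
length ≤ 300, and random matrices of up to 12 labels — sizes at which the
brute-force oracles they are checked against are trivially exact.  Golden
comparisons use 5×10⁻⁴ absolute tolerance after rounding to the printed
precision; ultrametricity is asserted to 1×10⁻⁹; triangle-inequality checks
allow 1×10⁻¹² for float association.

## Limitations

- Frame 0 is assumed; a sequence not starting at its first codon will be
  encoded, silently, on the wrong frame.
- WD's length sensitivity means partial sequences (like the bundled
  chimpanzee and gorilla entries) carry deviation attributable to
  truncation as well as substitution; this is faithful to the measure's
  definition, not corrected for.
- Only k = 3 non-overlapping words are counted; no other k, no overlapping
  windows, no alternative weighting schemes.
- Tree methods are limited to UPGMA/NJ without bootstrap support values.
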