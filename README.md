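# tripletwd

Alignment-free comparison of DNA coding sequences through a triplet-weight
2D graphical representation and a *weight deviation* similarity measure.

## The idea

Each of the 64 DNA triplets (the DNA counterparts of the mRNA codons) is
assigned a fixed real-valued weight Ψ.  The integer part of the weight
indexes the amino acid the triplet codes for (alanine = 1, arginine = 2, …,
methionine = 20, the three stop triplets = 21) and the fractional part
distinguishes synonymous triplets, e.g. Ψ(GCT) = 1.1, Ψ(GCC) = 1.2,
Ψ(ATG) = 20.1.  The table is built so that any two synonymous triplets are
always closer in weight than any two triplets coding different amino acids
(max within-group gap 0.5 < min between-group gap 0.7).

A coding sequence G = g₁…g_N read in frame 0 becomes M = ⌊N/3⌋ triplets
t₁…t_M and thence a 2D *plot set*

    Θ(G) = {(1, Ψ(t₁)), (2, Ψ(t₂)), …, (M, Ψ(t_M))},

a graphical fingerprint of the sequence.  Counting how often each canonical
triplet T₁…T₆₄ occurs gives a 64-vector profile ⟨Tᵢ, δ(Tᵢ)⟩, and two
sequences A, B with profiles X, Y are compared by the **weight deviation**

    WD(A, B) = ( Σᵢ₌₁⁶⁴ |Xᵢ − Yᵢ| · Ψ(Tᵢ) ) / 64,

a Ψ-weighted L1 metric on triplet counts — smaller means more similar.  No
alignment and no matrix algebra are required, so the cost is linear in
sequence length.  Distance matrices feed standard UPGMA or neighbor-joining
tree construction with Newick output.

The package bundles the classic benchmark for such measures: the complete
β-globin coding sequences of 11 species (human, chimpanzee, gorilla, black
lemur, Norway rat, house mouse, goat, bovine, rabbit, opossum, *Gallus*),
together with the published pairwise weight-deviation values for checking a
recomputation entry-for-entry.

## Worked example

```python
>>> import tripletwd as tw
>>> table = tw.build_weight_table()
>>> records = tw.load_beta_globin()
>>> matrix = tw.pairwise_matrix(records, table)
>>> round(matrix["Gorilla", "Chimpanzee"], 4)
1.1266
>>> round(matrix["Human", "Gorilla"], 4)
4.3359
>>> round(matrix["Human", "Chimpanzee"], 4)
5.25
>>> print(tw.to_newick(tw.build_tree(matrix, "upgma"))[:52])
(((((Black_lemur:2.844531,Rabbit:2.844531):1.405703,
```

Gorilla–chimpanzee, human–gorilla and human–chimpanzee are the three
smallest of the 55 pairwise distances — the three primates cluster before
anything else — while every distance from opossum or *Gallus* to any other
species exceeds 11, reflecting that *Gallus* is not a mammal and the
opossum is the most distant mammal in the set.

The same pipeline is available from the shell:

```
tripletwd fixtures export --out betaglobin.fasta
tripletwd encode  --in betaglobin.fasta --out-dir coords/ --plot
tripletwd compare --in betaglobin.fasta --out matrix.csv
tripletwd tree    --in matrix.csv --out tree.nwk --method upgma
tripletwd reproduce --out results/
```

`reproduce` runs everything on the bundled sequences and writes
`comparison.tsv`, which checks the recomputed matrix against the bundled
published values pair by pair:

```
45/55 pairs match published values; 10 mismatch(es) detailed in comparison.tsv
```

The ten mismatching pairs all involve *Gallus*: the published matrix was
evidently computed from a *Gallus* input whose triplet counts differ from
the published *Gallus* sequence by a single GAT/AGG codon (the residuals
are exactly ±(3.3±2.6)/64).  The sequences ship as published and the
discrepancy is reported, not patched; see `docs/methods.md` for the
analysis.

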