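# Methods

`asca` re-creates, desk-scale and fully tested, a comparative analysis that
is common in enzyme-family mining: align a protein family against a
reference whose active site is characterized, read off the residues every
homolog presents at the reference's active-site positions, organise those
"fingerprints" on a phylogeny, and use a diagnostic indel to split the
family into subfamilies before ranking divergent candidates.  The concrete
default configuration is the fungal vanillyl alcohol oxidase (VAO) family
with PsVAO as reference and bacterial eugenol oxidases as outgroup.

## The model of the data

The analysis assumes a family of homologous single-domain protein sequences
in which

- a small set of *first-shell* active-site positions is defined on a
  reference sequence in 1-based residue numbering and grouped into named
  functional clusters (defaults: A = para-substituent coordination, 4
  residues; H = covalent FAD binding, 3; P = phenolate binding, 5; T =
  substrate-tunnel gate, 3; W = catalytic/water activation, 6; 21 positions
  total);
- clade structure dominates sequence variation: members of a clade share
  characteristic active-site states, while background positions drift;
- one segment (the oligomerization loop) is present in part of the family
  and cleanly deleted in the rest, and this presence/absence is the
  subfamily criterion.

## Pipeline stages and numerical choices

**Deduplication.** A duplicate is exact residue-string identity; the first
record in input order is kept and every collapse is recorded.  Similarity
thresholds are deliberately avoided — near-identical homologs are data.

**Alignment.** A progressive aligner: 3-mer distance matrix
(`1 − shared/min` over distinct k-mer sets), UPGMA guide tree with ties
broken on the smallest leaf-index pair, then profile–profile merges with a
Gotoh three-state affine DP.  Scoring is BLOSUM62 with gap open −10 and gap
extend −1 (a gap run of length L costs `open + (L−1)·extend`); inside
profiles, an existing gap scores `extend` against a residue and 0 against a
gap, and column pairs score by average-of-pairs.  DP ties prefer
match > gap-in-second > gap-in-first, making the output deterministic.
All-gap columns arising from merges are deleted so the coordinate map stays
minimal.  The pairwise core is exact (verified against exhaustive
enumeration and an independent implementation); the multiple alignment is a
heuristic and is *not* claimed to reproduce any external aligner — imported
alignments (aligned FASTA/Clustal) flow through the identical downstream
path for users who prefer MAFFT/ClustalW/MEGA output.

**Coordinate map and fingerprints.** The k-th non-gap character of the
reference row maps residue k to its column; fingerprints read the target
row at those columns, with "-" reported where the target is gapped
(deletions are informative — the loop analysis depends on it).  In
fingerprint comparisons, "-" and X mismatch everything *including
themselves*: an ambiguous or absent residue is never evidence of
conservation.  Consequence: the Hamming distance is a true metric only on
gap/X-free fingerprints (symmetry and the triangle inequality always hold;
identity fails on opaque symbols by design).

**Tree.** p-distances (mismatches over mutually non-gap, non-X columns;
distance 1 when no column is comparable) and classic neighbor joining, with
Q-matrix ties broken on the smallest node-index pair and negative branch
estimates clamped to 0.  NJ is exact on additive matrices (tested to
1e-9).  Maximum-likelihood inference is out of scope; an external ML tree
can be imported as Newick.  Outgroup rooting requires the outgroup to be
one side of a bipartition and places the root at the midpoint of that
branch.

**Clades.** With `k` given, the k−1 longest internal ingroup branches are
cut and the components are the clades.  This matches how long inter-clade
stems look on a tree, but it is a heuristic: when NJ length noise makes a
spine edge (subtending two clades) longer than an individual clade stem,
one cut is spent on the spine and fewer, coarser groups come back.  The
subfamily assignment is robust to this (clades merge, loop states stay
consistent), but exact clade recovery is only guaranteed when inter-clade
branches clearly dominate.  An explicit membership file is the faithful
alternative and is warned about (not rejected) when a group is not
monophyletic.

**Loop and subfamilies.** Loop occupancy is the non-gap fraction over the
mapped columns of a configured reference span; a sequence is loop-positive
at occupancy ≥ 0.5.  A clade is loop-positive when ≥ 90% of members are,
loop-negative at ≤ 10%, otherwise mixed; subfamilies are the (at most two)
maximal groups of clades sharing a non-mixed state, and mixed clades are
reported unassigned.  The loop span is deliberately *configuration*, not a
packaged constant — it is structure-derived knowledge that differs per
family.  Thresholds make a by-inspection judgement testable; they are not
fitted to anything.

**Candidate ranking.** Plain Hamming distance of each fingerprint to the
reference fingerprint, optionally restricted to a cluster subset,
descending, ties by id.  No weighting is attempted because any weights
would pretend to knowledge (relative functional importance of positions)
the sequence analysis does not have.

## The synthetic family generator

The generator produces the structure the analysis assumes, with truth
tables for every stage.  A rooted tree with `n_clades` ingroup caterpillar
clades on a spine plus a monophyletic outgroup is built from explicit
branch lengths; the root sequence is uniform over the 20 amino acids except
at the 21 active-site positions, which the default scenario pins to the
reference residues so that clades without presets look like the reference
enzyme.  Each branch receives Poisson(rate × length × free sites)
substitutions, uniform over sites and over the 19 alternatives, never at
protected positions; each leaf's protected positions are then overwritten
by its clade preset; finally the loop span is deleted from clades not
carrying it.  The loop lives in the loop-bearing root (deletion, not
insertion) so reference numbering over the span stays well defined.

Default scenario: 7 ingroup clades × 4 leaves + 3 outgroup leaves (n = 31),
root length 560, rate 1.0 substitutions/site/unit length, intra-clade
branches 0.02, inter-clade 0.10 (5×), outgroup stem 0.20, loop at reference
525–552 present in C1–C6.  These sizes keep a full simulate-align-analyse
cycle around a second while giving ~4–30% pairwise divergence — enough for
clade structure without stressing the aligner.  The per-clade presets plant
the qualitative patterns described for the real family (e.g. C2: T459V;
C1: H61F, T459V, D409T; C6: H61F, D409E, F424A, I468, C470E; C7: H61M,
L316Q, D409R, F424G, T459C, C470E; outgroup: F424G, T459A).  Because the
published residue lists are internally inconsistent about positions 408/409
and I468/L468, the packaged config follows the explicit cluster listing
(409, 410; I468), and the "408" substitutions are planted at 409.  Note
that pinning the root to the reference states makes C6 differ from the
reference at 4 of its 5 preset positions (I468 coincides with the
reference state).

What the generator does *not* emulate: realistic substitution processes
(no rate matrix, no rate heterogeneity, no among-clade composition bias),
alignment-hostile indels other than the single clean loop, fragmentary or
mis-annotated database sequences, and paralog contamination.  Passing tests
therefore demonstrate that the pipeline's logic is correct under its own
assumptions — not that every real retrieval set will align and partition
this cleanly.

**"Mostly replaced" simplification.** Clade presets apply to every member
(probability 1.0 by default); the real family's "mostly" can be emulated by
lowering `preset_probability`, but tests use the deterministic setting so
recovery can be scored exactly.

## Determinism

Every stochastic element (root sequence, substitutions) flows from the
single integer seed through one `numpy` generator; the aligner, tree
builder and all tie-breaks are deterministic, so a fixed configuration
reproduces every artifact byte for byte.

## Known limitations

- Progressive alignment has no refinement pass; at divergence well beyond
  the simulated regime, fingerprint extraction inherits alignment error.
- Automatic clade cutting can merge clades (see above); k is a user choice,
  not inferred.
- p-distances saturate for deep divergence; NJ topology quality degrades
  accordingly.  Import an external tree for serious phylogenetics.
- The subfamily logic supports exactly one diagnostic indel; families with
  several informative indels need multiple runs with different loop spans.
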