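# trefoilkit

A toy, fully testable implementation of a bottom-up fold-mining workflow
for β-trefoil-like protein folds: filter structure-search hits, classify
domain-architecture novelty, build structure-based multiple alignments,
profile per-column mutation tolerance by Shannon entropy, and compare
core-position phylogenies against full-alignment phylogenies — all
exercised end to end on synthetic structure/sequence families with
planted ground truth, so no structure database or external search server
is required.

## Who this is for

Structural bioinformaticians who mine the PDB or predicted-structure
databases by fold-fold comparison and want the downstream analysis
stages — threshold filtering, representative selection, novelty
classification, conservation profiling, clade-purity scoring — as
reusable, tested library code with explicit contracts, plus a synthetic
data generator that plants the ground truth those stages are supposed to
recover.

## The analysis in brief

* **Filtering cascade.** A hit from a structure search is kept when
  `rmsd < rmsd_max` **and** `alnlen / qlen ≥ cov_min`. Two presets are
  built in: a strict first iteration (2.0 Å, 80%) to suppress false
  positives when searching experimental structures, and a relaxed second
  iteration (3.0 Å, 30%) that admits multi-domain proteins whose trefoil
  domain covers only part of the query. Rmsd is compared strictly,
  coverage inclusively: the boundary row at exactly 30% coverage is kept.
* **Superposition kernel.** Least-squares rigid superposition (Kabsch via
  SVD, reflections excluded), an iterative superpose-and-re-match
  structural aligner (dynamic programming on the Cα distance matrix with
  score `d_cut − d_ij`, monotone correspondence, multi-register restarts,
  annealed cutoff), and a reference-based (star) structure MSA.
* **Mutation tolerance.** Columns with ≥ 10% gaps are dropped; each
  remaining column gets a Shannon entropy `H = −Σ p_a log₂ p_a` over its
  non-gap residues. An invariant column scores 0 bits, a uniform
  20-residue column log₂20 ≈ 4.32 bits. The handful of low-entropy
  "core" positions (bottom-9, core bottom-7 by default) is extracted for
  a separate phylogeny.
* **Phylogenetics.** Neighbor joining on p-distances, exact on additive
  matrices and deterministic under an explicit tie-break. Clade purity:
  cut the tree into *k* groups at the *k−1* longest internal branches and
  report the fraction of leaves matching their group's plurality label —
  used to quantify whether a tree clusters by function or by kingdom.
* **Synthetic families.** Sequences evolve down a seeded random tree
  (uniform replacement over 20 amino acids; invariant or function-coded
  core columns); each taxon's structure is a pseudo-threefold-symmetric
  Cα template plus Gaussian noise proportional to its sequence
  divergence, which couples pairwise rmsd inversely to pairwise identity.

## Worked example

```
trefoilkit run-all --seed 1 --outdir demo_run
```

simulates a 64-member family (150 columns, 7 planted invariant core
positions), generates and filters synthetic search tables under both
presets, selects architecture representatives, classifies novelty
categories, builds the structure-based MSA, the entropy profile, and the
full and core-position trees. With seed 1 the run report includes:

```
filter_iteration1:  n_input 500  n_kept 147  (rejected: 205 by rmsd, 148 by coverage)
filter_iteration2:  n_input 500  n_kept 205  (rejected: 182 by rmsd, 113 by coverage)
structure_msa:      64 rows, width 140, 0 structures excluded
conservation:       150 columns in, 144 kept (<10% gaps), 9 low-entropy, 7 core
purity (k=4):       full tree   function 0.73  kingdom 0.28
                    core tree   function 0.67  kingdom 0.25
```

The seven detected core positions (`core_positions.txt`: 15, 52, 100,
105, 138, 141, 146) exactly equal the planted ones
(`planted_core.txt`) — the low-entropy selection recovered the simulated
structural core. Purity above ~0.7 for function labels versus ~0.28 for
kingdom labels says the tree clusters by function, as expected here
because the default generator ties function labels to the deepest clades
of the true tree. Every stage writes its artifact plus a JSON log line;
rerunning with the same seed is bit-identical.

The same stages are available individually (`simulate`, `parse`,
`filter`, `represent`, `classify`, `align`, `entropy`, `tree`,
`purity`), and as library functions.

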