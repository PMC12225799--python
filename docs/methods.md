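# Methods

This note records the models, conventions and numerical choices behind
trefoilkit, and what the synthetic-data experiments do and do not show.

## Filtering model

A search hit is a row `(target, qlen, alnlen, rmsd, taxname, taxlineage)`
in the Foldseek tabular dialect, or a DALI summary row (field 3 = rmsd,
field 4 = aligned length; the query length is supplied by the caller
because the summary table omits it). Coverage is always
`alnlen / qlen` — the query is the denominator in both presets. The keep
predicate is `rmsd < rmsd_max AND coverage >= cov_min`: rmsd strictly,
coverage inclusively, so a row at exactly the coverage floor passes.
Preset thresholds: iteration 1 = (2.0 Å, 0.80), iteration 2 =
(3.0 Å, 0.30). Rows with non-positive query length are data errors:
rejected and itemised in the report, never raised, so one bad row cannot
abort a batch. Filtering is idempotent and count-conserving
(kept + rejected = input), both tested.

Kingdom assignment scans the lineage ranks outermost-first against a
fixed vocabulary (bacteria, fungi, metazoa, plantae including
Viridiplantae/Streptophyta, and the common protist phyla for protozoa);
anything unmatched maps to "unknown", making the function total. The
kingdom-diversity summary exposes its coverage window as explicit
parameters rather than hard-coding one, because summaries of this shape
are legitimately reported over different windows (all hits, ≥30%, <30%).

## Superposition kernel

`kabsch` is the SVD form of least-squares rigid superposition. The
determinant of the rotation is forced to +1 — a reflection would invert
backbone chirality, which is never a valid protein superposition.
Collinear (rank-deficient) inputs are solved but flagged `degenerate`
(second singular value ≤ 1e-8 of the first). Tested against an
independently coded quaternion closed form (Horn's method) to 1e-8 on
random point sets, and for optimality against random rigid transforms.

`align_structures` is a sequence-independent pairwise aligner for Cα
traces, standing in for external fold-comparison engines at toy scale
(no claim of competitive accuracy; no Z-scores, no 3Di alphabet). It
works by alternating (i) superposition on the current residue
correspondence and (ii) extraction of a new correspondence from the
inter-structure distance matrix by dynamic programming, scoring a pair
as `dist_cutoff − d_ij` (default cutoff 5 Å), with matches below
positive score ineligible, no gap penalty, and strict monotonicity in
both indices. Two refinements matter in practice:

* **Multi-register restarts.** Seeds come from the best-superposing
  contiguous fragment pairs (fragment length 20, scanned on a stride of
  3), keeping up to five seeds whose diagonal registers differ by at
  least one fragment length. A pseudo-threefold-symmetric fold has decoy
  registers one lobe apart; restarting from several registers and
  keeping the final alignment with the highest total score
  `Σ max(cutoff − d, 0)` resolves them.
* **Annealed cutoff.** The first three iterations use 2.0×, 1.6× and
  1.3× the target cutoff. A 20-residue fragment superposition is only
  locally correct; applying the tight cutoff immediately locks the
  alignment into that local register.

Convergence is declared when the correspondence repeats; otherwise the
best result so far is returned with `converged=False`.

`reference_msa` is a star alignment: every structure is aligned pairwise
to one reference, giving one column per reference residue; unmatched
target residues are dropped (counted in a side report) and unmatched
reference positions become gaps. A star alignment was chosen over a
progressive-tree alignment because it is reproducible and
order-independent given the reference; the reference id is an explicit
required argument. Structures covering less than a configurable floor
(default 50%) of the reference are excluded and reported rather than
poisoning the alignment.

## Conservation profiling

Columns with a gap fraction **strictly below** 10% are retained (a
64-row column with 6 gaps, 9.4%, stays; with 7 gaps, 10.9%, goes; a
10-row column with exactly one gap goes). Entropy is Shannon entropy in
bits over the non-gap residues of a column; gaps carry no probability
mass. Bits were chosen because any fixed base is a monotone rescaling;
excluding gaps avoids conflating alignment coverage with sequence
variability, and is a minor choice anyway once columns are pre-filtered
to be nearly gap-free. An all-gap column has no defined entropy and
raises, carrying the column index.

Low-entropy selection supports both a numeric threshold and bottom-k
(default k=9 with a separate core k=7), with ties broken by lower
original column index so the selection is deterministic. Column indices
are always reported in the original (unfiltered) frame via the index map
returned by the gap filter.

## Phylogenetics

Distances are p-distances: mismatches over mutually non-gap columns.
Pairs with no comparable column are flagged missing and imputed with the
maximum observed distance (reported on the matrix). Trees come from
standard neighbor joining, chosen because it is deterministic (given the
explicit tie-break below), exact on additive matrices — which enables an
exhaustive-enumeration least-squares oracle over all fifteen 5-taxon
shapes — and conventional for structure-anchored alignments where no
substitution model is trusted. On ties in the Q-criterion the pair whose
lexicographically sorted cluster labels are smallest is joined (a
cluster is labelled by its smallest leaf label). Negative branch lengths
from the three-point formulas are clamped to zero and logged on the
tree. No rooting, bootstrap, or likelihood methods are in scope.

Clade purity cuts the tree into k groups by removing the k−1 longest
internal branches (length ties broken by the smallest leaf label on each
side) and reports the leaf-weighted plurality agreement of a label set
with the resulting groups. k equal to the leaf count is defined as the
singleton partition (purity 1) since no internal-branch cut can produce
it. When several removed branches meet at one internal node a component
can contain no leaves; such components are dropped, so fewer than k
non-empty groups may result. Nested cuts make purity monotone
non-decreasing in k, which is property-tested.

Newick reading/writing delegates to dendropy (labels with
metacharacters are quoted; branch lengths written with 12 significant
digits, round-tripping to 1e-9); a rooted degree-2 seed node is
collapsed on read so trees stay unrooted.

## Domain-architecture novelty

An architecture is an ordered list of named, non-overlapping domain
intervals; its signature is the name tuple in sequence order. Categories
for a trefoil + extra-domain protein against a catalog of structures
with known architectures: 1 if the extra domain appears in no catalog
structure; 2 if it appears but no such structure — even as its
full-length protein — also carries the trefoil; 3 if some catalog
structure pairs it with the trefoil (a full-length protein carrying both
also promotes to 3, per the rule that category 2 requires the trefoil to
be absent even from the full-length protein). Single-domain trefoils and
proteins whose complete signature is already catalogued are "known".
With several extra domains the protein takes the minimum (most novel)
category, recorded per-domain; the paper-scale analysis only ever has
one extra domain, so this aggregation is a package decision. Domain
identity is name equality on annotation tables — domain scanning (HMMs)
happens upstream and is out of scope. Growing the catalog can only move
a protein toward "known" (property-tested monotonicity).

## Synthetic data: what it emulates, and what it does not

The generator plants every signal the analysis stages are supposed to
recover; all of its mechanisms are the simplest that produce the
corresponding signal, with no claim of biological realism.

* **Template** — three 120°-rotated near-copies (0.15 Å jitter) of one
  compact self-avoiding Cα walk (3.8 Å steps, ≥3.3 Å non-adjacent
  separation, confined to a 10 Å ball, backtracking on dead ends),
  emulating the pseudo-threefold lobed architecture of a ~150-residue
  trefoil. The walk is irregular on purpose: a regular curve is
  self-similar at every register and makes fragment-seeded structural
  alignment ambiguous everywhere.
* **Tree** — random topology by sequential random attachment; pendant
  branch lengths i.i.d. Exponential with mean 0.1 expected
  substitutions per site.
* **Sequences** — uniform replacement over the 20 amino acids at rate
  1.5 per site per unit branch length along each branch. Together with
  the tree this makes pairwise identities span roughly 25–100%,
  emulating a fold family whose members are mostly far below 40%
  identity, and makes a background column invariant-by-chance (which
  would collide with the planted core) vanishingly rare.
* **Core columns** — 7 of 150 columns (seeded draw or explicit set)
  never substitute. In `invariant` mode they carry one residue across
  all taxa (zero entropy); in `function` mode each function group gets
  its own residue per core column (distinct across groups), so the core
  tracks function labels at ≈2 bits — still far below the ~3.5–4.2 bits
  of free columns.
* **Structures** — template coordinates plus isotropic Gaussian noise
  with standard deviation `2.0 Å × (realised sequence divergence from
  the root)`, the minimal mechanism coupling rmsd inversely to identity;
  resulting pairwise rmsds span roughly 0–3 Å.
* **Gaps** — i.i.d. per cell at 5% outside the core, and *physical*: a
  gapped cell's residue is absent from that taxon's structure, so the
  star alignment can rediscover the gap columns structurally.
* **Labels** — function (4 groups) and kingdom (5 kingdoms) are each
  either tied to the deepest clades of the true tree (cut at the longest
  internal branches) or assigned independently at random. Defaults:
  function from clades, kingdom random, invariant core. The
  convergent-evolution contrast scenario flips the switches: kingdom
  from clades (kingdom-correlated background divergence), function
  random, function-coded core — then the core-position tree clusters by
  function while the full alignment tree clusters by kingdom.
* **Search tables** — rmsd drawn uniformly up to 1.6× the preset cutoff
  and coverage around the floor, with ~10% of rows planted exactly on
  the coverage boundary (query lengths are multiples of ten so the
  boundary is exactly representable in floating point); each row's
  pass/fail label is recorded at generation time from the same
  predicate the filter applies.

Not emulated: realistic substitution matrices or rate heterogeneity
beyond the two-class core/free split, indel evolution with affine
histories, full-atom structures, correlated (domain-level) structural
divergence, and database-scale redundancy. Passing tests on this
generator therefore demonstrate that the pipeline's logic recovers
planted signals under its stated assumptions — not that it would mine a
real structure database with any particular sensitivity.

## Problem sizes and determinism

The simulation-based checks use 20 replicates of the default family (64
taxa × 150 columns) per scenario, 1,000-row × 5-seed search tables per
preset, 100 random point sets for the superposition oracle, and all 15
five-taxon shapes for the tree oracle; end-to-end pipeline tests run a
16-taxon family. Every stochastic component takes a NumPy
`default_rng` seed derived from a single user seed (`SeedSequence`
sub-streams in the pipeline and acceptance script), and a rerun with the
same seed is bit-identical, which the pipeline test verifies by
checksumming every artifact.

## Known limitations

* The structural aligner degrades at the top of the simulated noise
  range (per-coordinate σ ≈ 1.6 Å): i.i.d. noise leaves no locally rigid
  fragment to seed from, so the most diverged family members may align
  at reduced coverage and are then excluded from the star MSA by the
  coverage floor, as reported.
* The entropy-based core detector assumes the core is the lowest-entropy
  feature of the alignment. In the function-coded scenario core columns
  carry ≈2 bits and near-conserved background columns can undercut them,
  so analyses of that scenario use the planted core positions; detection
  is validated in the invariant-core scenario.
* Clade purity depends on the longest-branch cut heuristic; other
  operationalizations of "the k major clades" would give different
  absolute numbers, which is why only purity *comparisons* between label
  sets are interpreted.
* p-distance saturates for deeply diverged pairs; no distance correction
  is applied, consistent with treating the tree as descriptive rather
  than as an evolutionary estimate.
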