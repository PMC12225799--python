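"""Synthetic trefoil families, search tables and architecture fixtures.

Every downstream stage of the pipeline is exercised on data generated
here with planted ground truth, so the whole analysis runs and is
testable without structure databases or external search servers.

The generator emulates, at toy scale, the statistical features the
analysis depends on:

* a pseudo-threefold-symmetric Cα template (three near-identical lobes),
  standing in for a ~150-residue trefoil representative;
* a family of 64 sequences of ~150 columns evolved down a seeded random
  tree under a uniform-replacement substitution process with two
  per-site rate classes — a small set of invariant (or function-coded)
  "core" columns against freely mutating background columns;
* per-taxon structures obtained by perturbing the template's Cα
  coordinates with isotropic Gaussian noise whose scale grows linearly
  with that taxon's sequence divergence, which couples pairwise rmsd
  inversely to pairwise identity;
* search-result tables whose rows straddle the filtering thresholds,
  each carrying the exact pass/fail label the filter must reproduce;
* domain-architecture fixtures covering every novelty category.

No claim of biological realism is made anywhere: substitution is
uniform over the 20 amino acids, structure noise is isotropic, gaps are
i.i.d. per cell outside the core, and trees have i.i.d. exponential
branch lengths.  Each mechanism is the simplest one producing the
feature the corresponding analysis stage measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .architecture import (
    ArchitectureCatalog,
    CatalogEntry,
    DomainArchitecture,
)
from .errors import ConfigError, InvalidParameterError
from .mining import FilterPreset, hit_passes, preset as get_preset
from .phylogeny import PhyloTree, cut_tree
from .structure_io import (
    AA_ALPHABET,
    GAP,
    KINGDOMS,
    Msa,
    Residue,
    SearchHit,
    StructureRecord,
    kingdom_from_lineage,
)

#: Mean branch length (expected substitutions per site at rate 1) of the
#: random trees; chosen so pairwise identities span roughly 30-100%,
#: the identity range the mined families exhibit.
BRANCH_LENGTH_MEAN = 0.1

# Taxon-name / lineage vocabulary for synthetic search tables, one pool
# per kingdom of the five-kingdom vocabulary.
_LINEAGE_POOL: dict[str, list[tuple[str, str]]] = {
    "bacteria": [
        ("Escherichia coli", "cellular organisms;Bacteria;Proteobacteria"),
        ("Bacillus cereus", "cellular organisms;Bacteria;Firmicutes"),
        ("Streptomyces parvulus", "cellular organisms;Bacteria;Actinomycetota"),
    ],
    "fungi": [
        ("Clitocybe nebularis", "cellular organisms;Eukaryota;Fungi;Basidiomycota"),
        ("Aspergillus niger", "cellular organisms;Eukaryota;Fungi;Ascomycota"),
    ],
    "metazoa": [
        ("Homo sapiens", "cellular organisms;Eukaryota;Metazoa;Chordata"),
        ("Eisenia fetida", "cellular organisms;Eukaryota;Metazoa;Annelida"),
    ],
    "plantae": [
        ("Ricinus communis", "cellular organisms;Eukaryota;Viridiplantae;Streptophyta"),
        ("Sambucus ebulus", "cellular organisms;Eukaryota;Viridiplantae;Streptophyta"),
    ],
    "protozoa": [
        ("Plasmodium falciparum", "cellular organisms;Eukaryota;Alveolata;Apicomplexa"),
        ("Entamoeba histolytica", "cellular organisms;Eukaryota;Amoebozoa;Entamoebidae"),
    ],
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic family.

    ``core_positions`` may be given explicitly; by default ``core_size``
    columns are drawn (seeded) from the column range.  ``core_mode``
    selects how core columns behave: ``"invariant"`` plants one residue
    type per core column across all taxa (a zero-entropy core), while
    ``"function"`` plants one residue type per *function group* per core
    column, so the core columns track the function labels.
    ``function_from_clades`` / ``kingdom_from_clades`` choose whether a
    label set follows the deepest clades of the true tree (clade-
    correlated divergence) or is assigned independently of it.
    """

    seed: int
    n_taxa: int = 64
    n_columns: int = 150
    core_positions: frozenset[int] | None = None
    core_size: int = 7
    n_function_groups: int = 4
    substitution_rate: float = 1.5     # expected substitutions/site/unit branch
    structure_noise_scale: float = 2.0  # Å of Cα noise per unit sequence divergence
    gap_rate: float = 0.05             # per-cell gap probability outside the core
    core_mode: str = "invariant"
    function_from_clades: bool = True
    kingdom_from_clades: bool = False

    def validate(self) -> None:
        if self.n_taxa < 4:
            raise ConfigError("n_taxa must be at least 4")
        if self.n_columns < 1:
            raise ConfigError("n_columns must be positive")
        if self.core_positions is not None:
            bad = [p for p in self.core_positions if not (0 <= p < self.n_columns)]
            if bad:
                raise ConfigError(f"core positions out of range: {sorted(bad)}")
        elif not (0 <= self.core_size <= self.n_columns):
            raise ConfigError("core_size must be within the column range")
        if min(self.substitution_rate, self.structure_noise_scale, self.gap_rate) < 0:
            raise ConfigError("rates must be non-negative")
        if not (0 <= self.gap_rate < 1):
            raise ConfigError("gap_rate must be in [0, 1)")
        if self.core_mode not in ("invariant", "function"):
            raise ConfigError(f"unknown core_mode {self.core_mode!r}")
        if self.n_function_groups < 2:
            raise ConfigError("n_function_groups must be at least 2")
        if self.core_mode == "function" and self.n_function_groups > len(AA_ALPHABET):
            raise ConfigError("function-coded core needs n_function_groups <= 20")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update(overrides)
        if "core_positions" in data and data["core_positions"] is not None:
            data["core_positions"] = frozenset(int(p) for p in data["core_positions"])
        if "seed" not in data:
            raise ConfigError("seed is mandatory in simulation config")
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth shipped with every synthetic artifact."""

    core_positions: frozenset[int] = frozenset()
    true_tree: PhyloTree | None = None
    function_labels: dict[str, str] = field(default_factory=dict)
    kingdom_labels: dict[str, str] = field(default_factory=dict)
    pass_labels: tuple[bool, ...] = ()


# ---------------------------------------------------------------------------
# Template structure
# ---------------------------------------------------------------------------

def _lobe_walk(length: int, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding Cα walk: one irregular lobe.

    3.8 Å steps with directional persistence, confined to a ball and
    kept at least 3.3 Å from non-adjacent residues.  Irregularity
    matters: a regular curve is self-similar at every register, which
    would make fragment-based structural alignment of the template
    ambiguous everywhere.
    """
    step, min_sep, radius = 3.8, 3.3, 10.0
    pts = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    backtracks = 0
    while len(pts) < length:
        placed = None
        for attempt in range(100):
            # persistent proposals first; isotropic exploration when stuck
            spread = 0.9 if attempt < 40 else 3.0
            d = direction + rng.normal(scale=spread, size=3)
            d /= np.linalg.norm(d)
            cand = pts[-1] + step * d
            if np.linalg.norm(cand) > radius:
                # steer back toward the lobe centre
                pull = -pts[-1] / max(np.linalg.norm(pts[-1]), 1e-9)
                d = d + 1.5 * pull
                d /= np.linalg.norm(d)
                cand = pts[-1] + step * d
            clearance = (
                float(np.min(np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)))
                if len(pts) > 1
                else np.inf
            )
            if clearance >= min_sep and np.linalg.norm(cand) <= radius + 1.0:
                placed = cand
                break
        if placed is None and len(pts) > 1 and backtracks < 2000:
            del pts[-min(2, len(pts) - 1):]  # dead end: back up, try another route
            backtracks += 1
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            continue
        if placed is None:
            raise RuntimeError("self-avoiding walk failed; unreachable in practice")
        pts.append(placed)
        direction = (pts[-1] - pts[-2]) / step
    return np.array(pts)


def make_template_structure(n_residues: int, seed: int) -> StructureRecord:
    """A pseudo-trefoil Cα trace: three near-copies of one lobe.

    The lobe is an irregular compact self-avoiding walk with 3.8 Å Cα
    steps; the three lobes are 120° rotations of it about the
    pseudo-symmetry axis, each with small seeded jitter so the lobes
    superpose to well under 1 Å rmsd without being identical.
    Deterministic in the seed.
    """
    if n_residues < 9 or n_residues % 3 != 0:
        raise InvalidParameterError(
            "n_residues must be >= 9 and divisible by 3 (three lobes)"
        )
    rng = np.random.default_rng(seed)
    lobe_len = n_residues // 3
    lobe = _lobe_walk(lobe_len, rng) + np.array([10.0, 0.0, 0.0])
    coords: list[np.ndarray] = []
    for k in range(3):
        ang = 2 * math.pi * k / 3
        rot = np.array(
            [
                [math.cos(ang), -math.sin(ang), 0.0],
                [math.sin(ang), math.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        jitter = rng.normal(scale=0.15, size=lobe.shape)
        coords.append(lobe @ rot.T + jitter)
    xyz = np.vstack(coords)
    seq = rng.choice(list(AA_ALPHABET), size=n_residues)
    residues = tuple(
        Residue(number=i + 1, aa=str(seq[i]), xyz=tuple(float(v) for v in xyz[i]))
        for i in range(n_residues)
    )
    return StructureRecord(id=f"template{n_residues}s{seed}", residues=residues)


# ---------------------------------------------------------------------------
# Family evolution
# ---------------------------------------------------------------------------

def _random_tree(labels: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    """Random topology by sequential random attachment, Exp branch lengths."""
    n = len(labels)
    edges: list[list[float | int]] = []
    next_id = n

    def elen() -> float:
        return float(rng.exponential(BRANCH_LENGTH_MEAN))

    center = next_id
    next_id += 1
    for leaf in range(3):
        edges.append([center, leaf, elen()])
    for leaf in range(3, n):
        idx = int(rng.integers(len(edges)))
        u, v, w = edges.pop(idx)
        t = float(rng.uniform(0.2, 0.8))
        mid = next_id
        next_id += 1
        edges.append([u, mid, w * t])
        edges.append([mid, v, w * (1 - t)])
        edges.append([mid, leaf, elen()])
    return PhyloTree(
        edges=tuple((int(u), int(v), float(w)) for u, v, w in edges),
        leaf_labels={i: labels[i] for i in range(n)},
    )


def _balanced_labels(
    taxa: Sequence[str], values: Sequence[str], rng: np.random.Generator
) -> dict[str, str]:
    pool = [values[i % len(values)] for i in range(len(taxa))]
    rng.shuffle(pool)
    return dict(zip(taxa, pool))


def _clade_labels(
    tree: PhyloTree, values: Sequence[str], taxa: Sequence[str]
) -> dict[str, str]:
    groups = cut_tree(tree, len(values))
    groups.sort(key=lambda g: min(g))
    labels: dict[str, str] = {}
    for i, group in enumerate(groups):
        for taxon in group:
            labels[taxon] = values[i % len(values)]
    for taxon in taxa:  # leafless-component fallback cannot lose taxa, but be total
        labels.setdefault(taxon, values[0])
    return labels


def evolve_family(
    template: StructureRecord, config: SimulationConfig
) -> tuple[list[StructureRecord], Msa, GroundTruth]:
    """Evolve a structure/sequence family down a seeded random tree.

    The template sequence sits at an (arbitrary internal) root; along
    every branch of length t each free site substitutes with probability
    ``1 − exp(−rate·t)`` to a uniform random amino acid.  Core columns
    never substitute: in ``invariant`` mode they keep the template
    residue everywhere; in ``function`` mode each function group gets
    its own residue per core column (distinct across groups).  Each
    taxon's structure is the template plus isotropic Gaussian Cα noise
    with standard deviation ``structure_noise_scale`` times the taxon's
    realised sequence divergence from the template — the mechanism that
    couples rmsd to identity.  Gaps land i.i.d. per cell at ``gap_rate``,
    never at core columns.
    """
    config.validate()
    if len(template) != config.n_columns:
        raise ConfigError(
            f"template length {len(template)} != n_columns {config.n_columns}"
        )
    rng = np.random.default_rng(config.seed)
    n, width = config.n_taxa, config.n_columns
    taxa = tuple(f"T{i:03d}" for i in range(n))
    if config.core_positions is not None:
        core = frozenset(config.core_positions)
    else:
        core = frozenset(
            int(p) for p in rng.choice(width, size=config.core_size, replace=False)
        )
    tree = _random_tree(taxa, rng)

    # Simulate sequences root -> leaves over the unrooted tree.
    adj = tree.adjacency()
    root = n  # first internal node id
    aa_idx = {a: i for i, a in enumerate(AA_ALPHABET)}
    root_seq = np.array([aa_idx[a] for a in template.sequence], dtype=np.int64)
    free = np.array(sorted(set(range(width)) - core), dtype=np.int64)
    seqs: dict[int, np.ndarray] = {}
    stack: list[tuple[int, int | None, np.ndarray]] = [(root, None, root_seq)]
    while stack:
        node, parent, seq = stack.pop()
        if node in tree.leaf_labels:
            seqs[node] = seq
        for child, brlen in sorted(adj[node]):
            if child == parent:
                continue
            p_sub = 1.0 - math.exp(-config.substitution_rate * brlen)
            child_seq = seq.copy()
            if free.size and p_sub > 0:
                hit = free[rng.random(free.size) < p_sub]
                child_seq[hit] = rng.integers(0, len(AA_ALPHABET), size=hit.size)
            stack.append((child, node, child_seq))

    seq_matrix = np.stack([seqs[i] for i in range(n)])

    # Labels: clade-correlated or independent of the tree.
    function_values = tuple(f"F{g + 1}" for g in range(config.n_function_groups))
    if config.function_from_clades:
        function_labels = _clade_labels(tree, function_values, taxa)
    else:
        function_labels = _balanced_labels(taxa, function_values, rng)
    if config.kingdom_from_clades:
        kingdom_labels = _clade_labels(tree, KINGDOMS, taxa)
    else:
        kingdom_labels = _balanced_labels(taxa, KINGDOMS, rng)

    # Core columns: invariant, or coded by function group.
    core_sorted = sorted(core)
    if config.core_mode == "invariant":
        for c in core_sorted:
            seq_matrix[:, c] = root_seq[c]
    else:
        group_of = {f: g for g, f in enumerate(function_values)}
        for c in core_sorted:
            codes = rng.choice(
                len(AA_ALPHABET), size=config.n_function_groups, replace=False
            )
            for i, taxon in enumerate(taxa):
                seq_matrix[i, c] = codes[group_of[function_labels[taxon]]]

    # Gaps are physical: a gapped alignment cell means the residue is
    # absent from that taxon's structure.  Never at core columns.
    gap_mask = rng.random((n, width)) < config.gap_rate
    gap_mask[:, core_sorted] = False

    # Structures: template + noise scaled by realised divergence, with
    # gapped residues omitted (residue numbers stay column-aligned).
    divergence = (
        (seq_matrix[:, free] != root_seq[free]).mean(axis=1) if free.size else
        np.zeros(n)
    )
    base = template.coords
    structures: list[StructureRecord] = []
    for i, taxon in enumerate(taxa):
        sigma = config.structure_noise_scale * float(divergence[i])
        noisy = base + rng.normal(scale=sigma, size=base.shape) if sigma > 0 else base
        residues = tuple(
            Residue(number=j + 1, aa=AA_ALPHABET[seq_matrix[i, j]],
                    xyz=tuple(float(v) for v in noisy[j]))
            for j in range(width)
            if not gap_mask[i, j]
        )
        structures.append(StructureRecord(id=taxon, residues=residues))

    rows = []
    for i in range(n):
        chars = [
            GAP if gap_mask[i, j] else AA_ALPHABET[seq_matrix[i, j]]
            for j in range(width)
        ]
        rows.append("".join(chars))
    msa = Msa(taxa=taxa, rows=tuple(rows))
    truth = GroundTruth(
        core_positions=core,
        true_tree=tree,
        function_labels=function_labels,
        kingdom_labels=kingdom_labels,
    )
    return structures, msa, truth


# ---------------------------------------------------------------------------
# Search tables
# ---------------------------------------------------------------------------

def make_search_table(
    n_hits: int, preset: str | FilterPreset, seed: int
) -> tuple[list[SearchHit], GroundTruth]:
    """Synthetic search table straddling a preset's thresholds.

    Rmsd is drawn around the preset's cutoff and coverage around its
    floor, with a fraction of rows planted exactly on the coverage
    boundary (query lengths are multiples of ten so the boundary is
    representable exactly).  Each row's pass/fail label is recorded from
    the same predicate the filter applies, so the filter must agree
    exactly.  Lineages come from a fixed five-kingdom vocabulary.
    """
    p = get_preset(preset) if isinstance(preset, str) else preset
    if n_hits < 0:
        raise InvalidParameterError("n_hits must be non-negative")
    rng = np.random.default_rng(seed)
    hits: list[SearchHit] = []
    labels: list[bool] = []
    kingdoms = list(_LINEAGE_POOL)
    for i in range(n_hits):
        qlen = int(rng.integers(10, 31)) * 10
        if rng.random() < 0.10:
            alnlen = round(p.coverage_min * qlen)  # exactly on the boundary
        else:
            lo = max(0.05, p.coverage_min - 0.25)
            hi = min(1.0, p.coverage_min + 0.35)
            alnlen = max(1, round(float(rng.uniform(lo, hi)) * qlen))
        rmsd = round(float(rng.uniform(0.0, p.rmsd_max * 1.6)), 3)
        kingdom = kingdoms[int(rng.integers(len(kingdoms)))]
        name, lineage = _LINEAGE_POOL[kingdom][
            int(rng.integers(len(_LINEAGE_POOL[kingdom])))
        ]
        lineage_ranks = tuple(t for t in lineage.split(";"))
        hit = SearchHit(
            query_id="query",
            target_id=f"H{i:05d}",
            query_length=qlen,
            aligned_length=alnlen,
            rmsd=rmsd,
            taxon_name=name,
            tax_lineage=lineage_ranks,
            kingdom=kingdom_from_lineage(lineage_ranks),
        )
        hits.append(hit)
        labels.append(hit_passes(hit, p))
    return hits, GroundTruth(pass_labels=tuple(labels))


def write_ground_truth_table(
    hits: Sequence[SearchHit], truth: GroundTruth, path: str | Path
) -> None:
    """Plain TSV sidecar: target id and its planted pass label."""
    with open(path, "w") as handle:
        handle.write("target\tpass\n")
        for h, label in zip(hits, truth.pass_labels):
            handle.write(f"{h.target_id}\t{int(label)}\n")


# ---------------------------------------------------------------------------
# Architecture fixtures
# ---------------------------------------------------------------------------

def make_architecture_fixtures(
    seed: int,
) -> tuple[list[DomainArchitecture], ArchitectureCatalog, dict[str, int | str]]:
    """Proteins and a reference catalog forcing every novelty category.

    Covers: an extra domain absent from the catalog (category 1); an
    extra domain present in the catalog whose structures — including
    their full-length proteins — never carry the trefoil (category 2,
    the chitinase-style pattern); an extra domain already paired with
    the trefoil in one catalog structure (category 3); a single-domain
    trefoil and one whose full signature is already catalogued (known);
    and a multi-extra-domain protein taking the minimum category.
    """
    rng = np.random.default_rng(seed)

    def span(start: int, base_len: int) -> tuple[int, int]:
        return start, start + base_len + int(rng.integers(0, 20))

    t = "trefoil"
    archs = [
        DomainArchitecture("P_cat1", ((t, 1, 150), ("novel_dom", *span(160, 180)))),
        DomainArchitecture("P_cat2", ((t, 1, 150), ("chitinase", *span(160, 350)))),
        DomainArchitecture("P_cat3", ((t, 1, 150), ("ricin_lectin", *span(155, 130)))),
        DomainArchitecture("P_known", ((t, 1, 150),)),
        DomainArchitecture(
            "P_multi",
            ((t, 1, 150), ("chitinase", *span(160, 350)), ("novel_dom2", *span(600, 90))),
        ),
    ]
    entries = {
        # Chitinase-only structure; its full-length protein adds a
        # peptidase but still no trefoil -> drives category 2.
        "C_chit": CatalogEntry(
            architecture=DomainArchitecture("C_chit", (("chitinase", 1, 380),)),
            full_length_architecture=DomainArchitecture(
                "C_chit", (("chitinase", 1, 380), ("peptidase_m", 400, 700))
            ),
        ),
        # Structure already pairing trefoil with the lectin -> category 3.
        # Opposite domain order, so the signature itself is still novel.
        "C_lect": CatalogEntry(
            architecture=DomainArchitecture(
                "C_lect", (("ricin_lectin", 1, 140), (t, 150, 290))
            ),
            full_length_architecture=DomainArchitecture(
                "C_lect", (("ricin_lectin", 1, 140), (t, 150, 290))
            ),
        ),
        # Single-domain trefoil representative -> makes (trefoil,) known.
        "C_tref": CatalogEntry(
            architecture=DomainArchitecture("C_tref", ((t, 1, 150),)),
            full_length_architecture=DomainArchitecture("C_tref", ((t, 1, 150),)),
        ),
    }
    catalog = ArchitectureCatalog(entries=entries)
    expected: dict[str, int | str] = {
        "P_cat1": 1,
        "P_cat2": 2,
        "P_cat3": 3,
        "P_known": "known",
        "P_multi": 1,  # min over {chitinase: 2, novel_dom2: 1}
    }
    return archs, catalog, expected
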