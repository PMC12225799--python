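"""Distance-based phylogenetics over alignment columns.

Trees are built by neighbor joining on p-distances.  Neighbor joining is
exact on additive (tree-metric) inputs, deterministic here under an
explicit tie-break (lexicographically smallest leaf-label pair on equal
Q), and conventional for structure-anchored alignments where no
substitution model is trusted.  Clade structure is quantified by a
purity score: cut the tree into k groups by removing the k−1 longest
internal branches and report the fraction of leaves carried by each
group's plurality label — 1.0 means the labelling is perfectly
compatible with the k-clade structure of the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .errors import InvalidParameterError, NewickParseError, UnderdeterminedError
from .structure_io import GAP, Msa

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with a taxon order."""

    taxa: tuple[str, ...]
    matrix: np.ndarray
    missing_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise InvalidParameterError("matrix shape does not match taxa")
        if not np.allclose(m, m.T, atol=1e-12):
            raise InvalidParameterError("distance matrix is not symmetric")
        if (m < 0).any():
            raise InvalidParameterError("negative distances")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise InvalidParameterError("non-zero diagonal")

    def __len__(self) -> int:
        return len(self.taxa)


def p_distance(msa: Msa) -> DistanceMatrix:
    """Pairwise p-distance: mismatches over mutually non-gap columns.

    Pairs with no comparable column are flagged as missing and imputed
    with the maximum observed distance (1.0 if none is observed).
    """
    if msa.n_taxa < 2:
        raise UnderdeterminedError("p-distance needs at least 2 sequences")
    if msa.width < 1:
        raise UnderdeterminedError("p-distance needs at least 1 column")
    arr = msa.to_array()
    nongap = arr != GAP
    n = msa.n_taxa
    d = np.zeros((n, n))
    missing: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            comparable = int(both.sum())
            if comparable == 0:
                d[i, j] = d[j, i] = np.nan
                missing.append((msa.taxa[i], msa.taxa[j]))
            else:
                mism = int(((arr[i] != arr[j]) & both).sum())
                d[i, j] = d[j, i] = mism / comparable
    if missing:
        finite = d[np.isfinite(d)]
        fill = float(finite.max()) if finite.size else 1.0
        d = np.where(np.isnan(d), fill, d)
    return DistanceMatrix(taxa=msa.taxa, matrix=d, missing_pairs=tuple(missing))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloTree:
    """Unrooted weighted tree: edge list over integer nodes, labelled leaves."""

    edges: tuple[tuple[int, int, float], ...]
    leaf_labels: dict[int, str]
    clamp_log: tuple[tuple[str, float], ...] = field(default=(), compare=False)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaf_labels.values()))

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for u, v, w in self.edges:
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
        return adj

    def internal_edges(self) -> list[tuple[int, int, float]]:
        """Edges joining two non-leaf nodes."""
        return [
            (u, v, w)
            for u, v, w in self.edges
            if u not in self.leaf_labels and v not in self.leaf_labels
        ]

    def _side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels reachable from ``u`` when the edge (u, v) is cut."""
        adj = self.adjacency()
        seen = {v, u}
        stack = [u]
        out = []
        while stack:
            x = stack.pop()
            if x in self.leaf_labels:
                out.append(self.leaf_labels[x])
            for y, _ in adj.get(x, ()):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def splits(self) -> dict[frozenset[str], float]:
        """Branch length per bipartition, canonicalised to the side not
        containing the globally smallest leaf label.  Pendant edges map to
        singleton sides; internal edges to the corresponding split."""
        anchor = min(self.leaf_labels.values())
        out: dict[frozenset[str], float] = {}
        for u, v, w in self.edges:
            side = self._side_leaves(u, v)
            if anchor in side:
                side = self._side_leaves(v, u)
            out[side] = out.get(side, 0.0) + w
        return out


def trees_equal(a: PhyloTree, b: PhyloTree, tol: float = 1e-9) -> bool:
    """Topology and branch-length equality of two unrooted trees."""
    if set(a.leaf_labels.values()) != set(b.leaf_labels.values()):
        return False
    sa, sb = a.splits(), b.splits()
    if set(sa) != set(sb):
        return False
    return all(abs(sa[s] - sb[s]) <= tol for s in sa)


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining with a deterministic tie-break.

    At each step the pair minimising the Q-criterion is joined; on Q
    ties the pair whose (lexicographically sorted) cluster labels are
    smallest wins, where a cluster is labelled by its smallest leaf
    label.  Branch lengths come from the three-point formulas; negative
    lengths are clamped to 0 and the deficit logged on the tree.
    """
    n = len(d)
    if n < 3:
        raise UnderdeterminedError("neighbor joining needs at least 3 taxa")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.matrix[i, j])

    def dd(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(n))
    clabel = {i: d.taxa[i] for i in range(n)}
    leaf_labels = {i: d.taxa[i] for i in range(n)}
    next_id = n
    edges: list[tuple[int, int, float]] = []
    clamps: list[tuple[str, float]] = []

    def clamp(node_label: str, length: float) -> float:
        if length < 0:
            clamps.append((node_label, length))
            logger.debug("clamped negative branch %s: %.3g", node_label, length)
            return 0.0
        return length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dd(i, k) for k in active if k != i) for i in active}
        best_q = None
        best_pair = None
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dd(i, j) - r[i] - r[j]
                key = tuple(sorted((clabel[i], clabel[j])))
                if best_q is None or q < best_q or (q == best_q and key < best_key):
                    best_q, best_pair, best_key = q, (i, j), key
        i, j = best_pair
        dij = dd(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(clabel[i], li)
        lj = clamp(clabel[j], lj)
        u = next_id
        next_id += 1
        edges.append((u, i, li))
        edges.append((u, j, lj))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dd(i, k) + dd(j, k) - dij)
            dist[(min(u, k), max(u, k))] = duk
        clabel[u] = min(clabel[i], clabel[j])
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    v = next_id
    la = 0.5 * (dd(a, b) + dd(a, c) - dd(b, c))
    lb = 0.5 * (dd(a, b) + dd(b, c) - dd(a, c))
    lc = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
    edges.append((v, a, clamp(clabel[a], la)))
    edges.append((v, b, clamp(clabel[b], lb)))
    edges.append((v, c, clamp(clabel[c], lc)))
    return PhyloTree(edges=tuple(edges), leaf_labels=leaf_labels, clamp_log=tuple(clamps))


# ---------------------------------------------------------------------------
# Clade purity
# ---------------------------------------------------------------------------

def cut_tree(tree: PhyloTree, k: int) -> list[set[str]]:
    """Cut into k groups by removing the k−1 longest internal branches.

    Length ties break deterministically on the lexicographic pair of the
    smallest leaf label on each side of the branch.  Components left
    without leaves (possible when several cut edges meet at one internal
    node) are dropped, so fewer than k non-empty groups may return.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    internal = tree.internal_edges()
    if k - 1 > len(internal):
        raise InvalidParameterError(
            f"cannot cut into {k} groups: only {len(internal)} internal branches"
        )
    keyed = []
    for u, v, w in internal:
        side_u = tree._side_leaves(u, v)
        side_v = tree._side_leaves(v, u)
        tiebreak = tuple(sorted((min(side_u), min(side_v))))
        keyed.append(((-w,) + tiebreak, (u, v)))
    keyed.sort()
    removed = {frozenset(e) for _, e in keyed[: k - 1]}
    adj = tree.adjacency()
    seen: set[int] = set()
    groups: list[set[str]] = []
    for start in adj:
        if start in seen:
            continue
        seen.add(start)
        stack = [start]
        leaves: set[str] = set()
        while stack:
            x = stack.pop()
            if x in tree.leaf_labels:
                leaves.add(tree.leaf_labels[x])
            for y, _ in adj.get(x, ()):
                if y not in seen and frozenset((x, y)) not in removed:
                    seen.add(y)
                    stack.append(y)
        if leaves:
            groups.append(leaves)
    return groups


def clade_purity(tree: PhyloTree, labels: Mapping[str, str], k: int) -> float:
    """Fraction of leaves matching their group's plurality label.

    Groups come from :func:`cut_tree`.  ``k`` equal to the leaf count is
    the singleton partition and trivially pure.
    """
    leaves = set(tree.leaf_labels.values())
    missing = leaves - set(labels)
    if missing:
        raise InvalidParameterError(f"labels missing for leaves: {sorted(missing)[:5]}")
    if not (2 <= k <= len(leaves)):
        raise InvalidParameterError("k must be between 2 and the leaf count")
    if k == len(leaves):
        return 1.0
    groups = cut_tree(tree, k)
    plurality = 0
    for g in groups:
        counts: dict[str, int] = {}
        for leaf in g:
            counts[labels[leaf]] = counts.get(labels[leaf], 0) + 1
        plurality += max(counts.values())
    return plurality / len(leaves)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _to_dendropy(tree: PhyloTree) -> dendropy.Tree:
    adj = tree.adjacency()
    internal = [nid for nid in adj if nid not in tree.leaf_labels]
    root_id = max(internal) if internal else next(iter(adj))
    taxon_ns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxon_ns)

    def build(node_id: int, parent_id: int | None, length: float | None):
        node = dendropy.Node()
        if node_id in tree.leaf_labels:
            node.taxon = taxon_ns.require_taxon(label=tree.leaf_labels[node_id])
        node.edge.length = length
        for child, w in sorted(adj.get(node_id, ())):
            if child == parent_id:
                continue
            node.add_child(build(child, node_id, w))
        return node

    dtree.seed_node = build(root_id, None, None)
    dtree.is_rooted = False
    return dtree


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    ids: dict[int, int] = {}
    edges: list[tuple[int, int, float]] = []
    leaf_labels: dict[int, str] = {}
    counter = 0

    def nid(node) -> int:
        nonlocal counter
        key = id(node)
        if key not in ids:
            ids[key] = counter
            counter += 1
        return ids[key]

    for node in dtree.preorder_node_iter():
        i = nid(node)
        if node.is_leaf():
            label = node.taxon.label if node.taxon else ""
            leaf_labels[i] = label
        if node.parent_node is not None:
            w = node.edge.length if node.edge.length is not None else 0.0
            edges.append((nid(node.parent_node), i, float(w)))
    # A rooted (degree-2) seed node is collapsed to keep the tree unrooted.
    seed = dtree.seed_node
    children = seed.child_nodes()
    if len(children) == 2 and nid(seed) not in leaf_labels:
        s = nid(seed)
        (a, b) = (nid(children[0]), nid(children[1]))
        wa = next(w for u, v, w in edges if {u, v} == {s, a})
        wb = next(w for u, v, w in edges if {u, v} == {s, b})
        edges = [e for e in edges if s not in e[:2]]
        edges.append((a, b, wa + wb))
    return PhyloTree(edges=tuple(edges), leaf_labels=leaf_labels)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write one Newick line; labels quoted when they need it."""
    dtree = _to_dendropy(tree)
    s = dtree.as_string(schema="newick", suppress_rooting=True,
                        preserve_spaces=True,
                        real_value_format_specifier=".12g")
    with open(path, "w") as handle:
        handle.write(s if s.endswith("\n") else s + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    """Parse one Newick tree; malformed input raises with a locator."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick in {path}: {exc}") from None
    return _from_dendropy(dtree)
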