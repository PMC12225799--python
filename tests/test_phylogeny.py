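import itertools
import math

import numpy as np
import pytest

from trefoilkit.errors import (
    InvalidParameterError,
    NewickParseError,
    UnderdeterminedError,
)
from trefoilkit.phylogeny import (
    DistanceMatrix,
    PhyloTree,
    clade_purity,
    cut_tree,
    neighbor_joining,
    p_distance,
    read_newick,
    trees_equal,
    write_newick,
)
from trefoilkit.structure_io import Msa


# ---------------------------------------------------------------------------
# Five-taxon oracle: exhaustive topology enumeration + least-squares fit
# ---------------------------------------------------------------------------

TAXA5 = ("A", "B", "C", "D", "E")


def five_taxon_topologies():
    """All 15 unrooted binary shapes on 5 leaves, as (cherry1, cherry2)."""
    seen = set()
    out = []
    for cherry1 in itertools.combinations(range(5), 2):
        rest = [i for i in range(5) if i not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            key = frozenset((frozenset(cherry1), frozenset(cherry2)))
            if key in seen:
                continue
            seen.add(key)
            out.append((cherry1, cherry2))
    assert len(out) == 15
    return out


def topology_tree(cherry1, cherry2, lengths):
    """Build the PhyloTree for one 5-leaf shape.

    ``lengths``: 5 pendant lengths (leaf order) then the 2 internal
    lengths (cherry1 side, cherry2 side).
    """
    (a, b), (c, d) = cherry1, cherry2
    e = next(i for i in range(5) if i not in (*cherry1, *cherry2))
    u, v, m = 5, 6, 7
    edges = (
        (u, a, lengths[a]),
        (u, b, lengths[b]),
        (v, c, lengths[c]),
        (v, d, lengths[d]),
        (m, e, lengths[e]),
        (m, u, lengths[5]),
        (m, v, lengths[6]),
    )
    return PhyloTree(edges=edges, leaf_labels={i: TAXA5[i] for i in range(5)})


def tree_distance_matrix(tree):
    """Path-length distances between leaves (the induced additive metric)."""
    adj = tree.adjacency()
    labels = sorted(tree.leaf_labels.values())
    node_of = {lab: nid for nid, lab in tree.leaf_labels.items()}
    n = len(labels)
    d = np.zeros((n, n))
    for i, lab in enumerate(labels):
        dist = {node_of[lab]: 0.0}
        stack = [node_of[lab]]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, lab2 in enumerate(labels):
            d[i, j] = dist[node_of[lab2]]
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa=tuple(labels), matrix=(d + d.T) / 2)


def least_squares_fit(cherry1, cherry2, dm):
    """Least-squares branch lengths of one shape; returns (residual, tree)."""
    pair_index = {p: r for r, p in enumerate(itertools.combinations(range(5), 2))}
    (a, b), (c, d) = cherry1, cherry2
    e = next(i for i in range(5) if i not in (*cherry1, *cherry2))
    # columns: 5 pendant + internal(u-m), internal(v-m)
    design = np.zeros((10, 7))
    path_edges = {}
    for i, j in itertools.combinations(range(5), 2):
        cols = [i, j]
        side_i = 0 if i in (a, b) else (1 if i in (c, d) else None)
        side_j = 0 if j in (a, b) else (1 if j in (c, d) else None)
        if side_i != side_j:
            if side_i is not None:
                cols.append(5 + side_i)
            if side_j is not None:
                cols.append(5 + side_j)
        path_edges[(i, j)] = cols
        for c_ in cols:
            design[pair_index[(i, j)], c_] = 1.0
    order = {lab: k for k, lab in enumerate(dm.taxa)}
    y = np.array(
        [dm.matrix[order[TAXA5[i]], order[TAXA5[j]]]
         for i, j in itertools.combinations(range(5), 2)]
    )
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    residual = float(np.linalg.norm(design @ beta - y))
    return residual, topology_tree(cherry1, cherry2, beta)


@pytest.mark.parametrize("cherry1, cherry2", five_taxon_topologies())
def test_nj_exact_on_additive_matrices(cherry1, cherry2):
    """NJ recovers every 5-taxon shape and its branch lengths from the
    induced tree metric, agreeing with the exhaustive least-squares oracle."""
    rng = np.random.default_rng(hash((cherry1, cherry2)) % 2**31)
    lengths = rng.uniform(0.1, 1.0, size=7)
    true = topology_tree(cherry1, cherry2, lengths)
    dm = tree_distance_matrix(true)
    nj = neighbor_joining(dm)
    assert trees_equal(nj, true, tol=1e-9)
    # oracle: the generating shape fits with zero residual and the same
    # branch lengths; every other shape fits strictly worse
    best = sorted(
        (least_squares_fit(c1, c2, dm)[0], (c1, c2))
        for c1, c2 in five_taxon_topologies()
    )
    assert best[0][1] == (cherry1, cherry2)
    assert best[0][0] == pytest.approx(0.0, abs=1e-9)
    residual, fitted = least_squares_fit(cherry1, cherry2, dm)
    assert trees_equal(fitted, nj, tol=1e-9)


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = neighbor_joining(DistanceMatrix(taxa=("A", "B", "C"), matrix=d))
    splits = tree.splits()
    assert splits[frozenset({"B"})] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
    assert splits[frozenset({"C"})] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))
    # pendant of A is canonicalised as the complement side {B, C}
    assert splits[frozenset({"B", "C"})] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))


def test_nj_deterministic_under_equal_distances():
    d = np.ones((4, 4)) - np.eye(4)
    dm = DistanceMatrix(taxa=("a", "b", "c", "d"), matrix=d)
    t1 = neighbor_joining(dm)
    t2 = neighbor_joining(dm)
    assert trees_equal(t1, t2, tol=0.0)
    assert t1.n_leaves == 4


def test_nj_matches_independent_library_implementation():
    """Cross-check against scikit-bio's NJ on a perturbed additive matrix."""
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(2024)
    true = topology_tree((0, 1), (2, 3), rng.uniform(0.2, 1.0, size=7))
    dm = tree_distance_matrix(true)
    noise = rng.uniform(0, 0.01, size=dm.matrix.shape)
    noisy = dm.matrix + noise + noise.T
    np.fill_diagonal(noisy, 0.0)
    mine = neighbor_joining(DistanceMatrix(taxa=dm.taxa, matrix=noisy))
    theirs = read_newick_string(
        str(skbio_nj(skbio.DistanceMatrix(noisy, ids=list(dm.taxa))))
    )
    assert set(mine.splits()) == set(theirs.splits())


def read_newick_string(s):
    import io
    import dendropy
    from trefoilkit.phylogeny import _from_dendropy

    return _from_dendropy(
        dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    )


def test_nj_rejects_fewer_than_three_taxa():
    d = np.array([[0.0, 1.0], [1.0, 0.0]])
    with pytest.raises(UnderdeterminedError):
        neighbor_joining(DistanceMatrix(taxa=("a", "b"), matrix=d))


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

class TestPDistance:
    def test_identical_rows_zero(self):
        msa = Msa(taxa=("a", "b"), rows=("ACDE", "ACDE"))
        assert p_distance(msa).matrix[0, 1] == 0.0

    def test_mismatch_fraction(self):
        msa = Msa(taxa=("a", "b"), rows=("ACDEFGHIKL", "ACDEFGHACC"))
        assert p_distance(msa).matrix[0, 1] == pytest.approx(0.3)

    def test_disjoint_gap_pattern_flagged_missing(self):
        msa = Msa(taxa=("a", "b", "c"), rows=("A-", "-A", "AA"))
        dm = p_distance(msa)
        assert ("a", "b") in dm.missing_pairs
        finite_max = max(dm.matrix[0, 2], dm.matrix[1, 2])
        assert dm.matrix[0, 1] == finite_max

    def test_single_row_rejected(self):
        with pytest.raises(UnderdeterminedError):
            p_distance(Msa(taxa=("a",), rows=("ACDE",)))


# ---------------------------------------------------------------------------
# Clade purity
# ---------------------------------------------------------------------------

def random_tree(seed, n=16):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 8))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    taxa = tuple(f"L{i:02d}" for i in range(n))
    return neighbor_joining(DistanceMatrix(taxa=taxa, matrix=d))


class TestCladePurity:
    def test_constant_labels_perfectly_pure(self):
        tree = random_tree(0)
        labels = {lab: "x" for lab in tree.leaf_labels.values()}
        for k in (2, 4, 8):
            assert clade_purity(tree, labels, k) == 1.0

    def test_singleton_partition_pure(self):
        tree = random_tree(1)
        labels = {lab: lab for lab in tree.leaf_labels.values()}
        assert clade_purity(tree, labels, tree.n_leaves) == 1.0

    def test_monotone_in_k_for_nested_cuts(self):
        tree = random_tree(2)
        rng = np.random.default_rng(3)
        labels = {
            lab: f"g{rng.integers(3)}" for lab in sorted(tree.leaf_labels.values())
        }
        values = [clade_purity(tree, labels, k) for k in range(2, 12)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_purity_bounded(self):
        tree = random_tree(4)
        rng = np.random.default_rng(5)
        labels = {
            lab: f"g{rng.integers(4)}" for lab in sorted(tree.leaf_labels.values())
        }
        p = clade_purity(tree, labels, 4)
        assert 0.0 < p <= 1.0

    def test_too_many_groups_rejected(self):
        tree = random_tree(6, n=5)
        labels = {lab: "x" for lab in tree.leaf_labels.values()}
        with pytest.raises(InvalidParameterError):
            clade_purity(tree, labels, 4 + 2)  # 5 leaves: k=6 out of range

    def test_missing_labels_rejected(self):
        tree = random_tree(7)
        with pytest.raises(InvalidParameterError):
            clade_purity(tree, {}, 2)


def test_cut_tree_group_count():
    tree = random_tree(8, n=20)
    groups = cut_tree(tree, 4)
    assert sum(len(g) for g in groups) == 20
    assert len(groups) <= 4


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

class TestNewick:
    def test_roundtrip_five_taxon_fixture(self, tmp_path):
        true = topology_tree((0, 1), (2, 3), [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        path = tmp_path / "t.nwk"
        write_newick(true, path)
        back = read_newick(path)
        assert trees_equal(true, back, tol=1e-9)

    def test_three_leaf_star(self, tmp_path):
        path = tmp_path / "star.nwk"
        path.write_text("(A,B,C);\n")
        tree = read_newick(path)
        assert tree.n_leaves == 3
        assert len(tree.edges) == 3

    def test_unbalanced_parenthesis_rejected(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A,B,C);\n")
        with pytest.raises(NewickParseError):
            read_newick(path)

    def test_quoted_labels_survive(self, tmp_path):
        tree = PhyloTree(
            edges=((3, 0, 0.1), (3, 1, 0.2), (3, 2, 0.3)),
            leaf_labels={0: "needs space", 1: "semi;colon", 2: "plain"},
        )
        path = tmp_path / "quoted.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert set(back.leaf_labels.values()) == {"needs space", "semi;colon", "plain"}
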