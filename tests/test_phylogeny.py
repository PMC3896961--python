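"""UPGMA / neighbor-joining tree building and Newick serialization.

Cross-checks: UPGMA cophenetic distances against scipy's average-linkage
implementation, neighbor joining against additive matrices generated from
random trees (topology recovery), and Newick output against dendropy's
parser.
"""

import numpy as np
import pytest

import dendropy
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from tripletwd.phylogeny import Tree, build_tree, neighbor_joining, to_newick, upgma
from tripletwd.similarity import DistanceMatrix


def random_distance_matrix(rng, n):
    d = rng.uniform(1.0, 10.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = tuple(f"L{i:02d}" for i in range(n))
    return DistanceMatrix(labels=labels, values=d)


def pairwise_path_lengths(tree):
    """Leaf-to-leaf path lengths through the tree (cophenetic distances).

    For each pair the lowest common ancestor is the smallest clade containing
    both leaves; the path length is depth(a) + depth(b) - 2 * depth(LCA).
    """
    depths = tree.leaf_depths()
    clade_depth = _clade_depths(tree)
    lca = {}
    for leaves in sorted(clade_depth, key=len):
        for a in sorted(leaves):
            for b in sorted(leaves):
                if a < b and (a, b) not in lca:
                    lca[(a, b)] = leaves
    return {
        (a, b): depths[a] + depths[b] - 2 * clade_depth[leaves]
        for (a, b), leaves in lca.items()
    }


def _clade_depths(tree):
    """Depth (root-to-node path length) of each internal clade."""
    out = {}

    def walk(c, depth):
        if c.is_leaf():
            return frozenset([c.name])
        leaves = frozenset()
        for ch in c.children:
            leaves |= walk(ch, depth + (ch.branch_length or 0.0))
        out[leaves] = depth
        return leaves

    walk(tree.root, 0.0)
    return out


def test_two_leaf_upgma_closed_form():
    m = DistanceMatrix(labels=("A", "B"), values=np.array([[0.0, 2.0], [2.0, 0.0]]))
    tree = build_tree(m, "upgma")
    assert to_newick(tree) == "(A:1.000000,B:1.000000);"


def test_three_leaf_upgma_single_step_by_hand():
    values = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
    m = DistanceMatrix(labels=("A", "B", "C"), values=values)
    tree = build_tree(m, "upgma")
    # A and B join first at height 1; C joins at height 2
    depths = tree.leaf_depths()
    assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}
    assert frozenset({"A", "B"}) in tree.clades()
    assert to_newick(tree) == "((A:1.000000,B:1.000000):1.000000,C:2.000000);"


def test_upgma_is_ultrametric_on_random_matrices():
    rng = np.random.default_rng(11)
    for n in (4, 7, 12):
        m = random_distance_matrix(rng, n)
        tree = upgma(m)
        depths = list(tree.leaf_depths().values())
        assert max(depths) - min(depths) < 1e-9
        assert sorted(tree.leaf_names()) == sorted(m.labels)


def test_upgma_matches_scipy_average_linkage():
    """Cophenetic distances agree with scipy's average-linkage clustering."""
    rng = np.random.default_rng(3)
    for n in (5, 8):
        m = random_distance_matrix(rng, n)
        tree = upgma(m)
        ours = pairwise_path_lengths(tree)
        z = linkage(squareform(m.values), method="average")
        coph = squareform(cophenet(z))
        for i, a in enumerate(m.labels):
            for j in range(i + 1, n):
                b = m.labels[j]
                key = (a, b) if a < b else (b, a)
                assert ours[key] == pytest.approx(coph[i, j], abs=1e-9)


def test_neighbor_joining_recovers_additive_topologies():
    """On distances that are exactly additive on a tree, NJ finds its splits."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        n = 7
        labels = [f"L{i:02d}" for i in range(n)]
        # build a random tree by joining random subtrees, tracking each
        # leaf's depth, leaf-to-leaf distances, and the splits created
        depth = {lab: 0.0 for lab in labels}
        dist = {}
        splits = []
        parts = [{lab} for lab in labels]
        while len(parts) > 1:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            bi, bj = rng.uniform(0.5, 2.0, size=2)
            for x in parts[i]:
                depth[x] += bi
            for x in parts[j]:
                depth[x] += bj
            for x in parts[i]:
                for y in parts[j]:
                    dist[(x, y) if x < y else (y, x)] = depth[x] + depth[y]
            merged = parts[i] | parts[j]
            if 1 < len(parts[i]) < n - 1:
                splits.append(frozenset(parts[i]))
            if 1 < len(parts[j]) < n - 1:
                splits.append(frozenset(parts[j]))
            parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
        values = np.zeros((n, n))
        for a_i, a in enumerate(labels):
            for b_i in range(a_i + 1, n):
                b = labels[b_i]
                values[a_i, b_i] = values[b_i, a_i] = dist[(a, b)]
        m = DistanceMatrix(labels=tuple(labels), values=values)
        tree = neighbor_joining(m)
        leafset = frozenset(labels)
        nj_splits = {
            min(c, leafset - c, key=sorted)
            for c in tree.clades()
            if 1 < len(c) < n - 1
        }
        expected = {min(s, leafset - s, key=sorted) for s in splits}
        assert expected <= nj_splits


def test_newick_round_trip_via_dendropy():
    rng = np.random.default_rng(9)
    m = random_distance_matrix(rng, 6)
    for method in ("upgma", "nj"):
        tree = build_tree(m, method)
        nwk = to_newick(tree)
        assert nwk.endswith(";")
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(m.labels)
        if method == "upgma":
            # parsed branch lengths preserve ultrametric depths
            depths = {
                leaf.taxon.label: leaf.distance_from_root()
                for leaf in parsed.leaf_node_iter()
            }
            assert max(depths.values()) - min(depths.values()) < 1e-5


def test_newick_quotes_names_with_spaces():
    m = DistanceMatrix(
        labels=("Black lemur", "Norway rat"),
        values=np.array([[0.0, 1.0], [1.0, 0.0]]),
    )
    nwk = to_newick(build_tree(m, "upgma"))
    assert "'Black lemur'" in nwk and "'Norway rat'" in nwk
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert sorted(t.label for t in parsed.taxon_namespace) == ["Black lemur", "Norway rat"]


def test_tie_break_is_deterministic():
    values = np.ones((4, 4)) - np.eye(4)
    m = DistanceMatrix(labels=("d", "c", "b", "a"), values=values)
    first = to_newick(build_tree(m, "upgma"))
    second = to_newick(build_tree(m, "upgma"))
    assert first == second
    # lexicographically smallest pair (a, b) merges first
    tree = build_tree(m, "upgma")
    assert frozenset({"a", "b"}) in tree.clades()


def test_too_few_labels_raise():
    m2 = DistanceMatrix(labels=("a", "b"), values=np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError):
        neighbor_joining(m2)
    with pytest.raises(ValueError):
        build_tree(m2, "unknown-method")


def test_nj_branch_lengths_are_nonnegative():
    rng = np.random.default_rng(13)
    for _ in range(5):
        m = random_distance_matrix(rng, 8)
        tree = neighbor_joining(m)

        def walk(c):
            if c.branch_length is not None:
                assert c.branch_length >= 0.0
            for ch in c.children:
                walk(ch)

        walk(tree.root)
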