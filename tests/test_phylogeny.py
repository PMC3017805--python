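import math

import numpy as np
import pytest

from flcdnakit.phylogeny import (
    ConcatenatedAlignment,
    TreeNode,
    bipartitions,
    bootstrap_support,
    build_distance_matrix,
    jc_distance,
    neighbor_joining,
    root_at_outgroup,
)
from flcdnakit.synthetic_data import simulate_jc_alignment


def _node(name=None, length=0.0, children=None):
    n = TreeNode(name=name, length=length)
    n.children = children or []
    return n


def _tree_distances(tree):
    """Leaf-to-leaf path lengths of a tree (oracle for additivity)."""
    dists = {}

    def walk(node, acc):
        if node.is_leaf:
            dists[node.name] = acc
            return
        for c in node.children:
            walk(c, acc + c.length)

    # distances via common root: d(a,b) = depth(a)+depth(b)-2*depth(lca);
    # easier: brute force over pairs using paths
    paths = {}

    def collect(node, path):
        if node.is_leaf:
            paths[node.name] = path + [node]
            return
        for c in node.children:
            collect(c, path + [node])

    collect(tree, [])
    out = {}
    for a in paths:
        for b in paths:
            if a >= b:
                continue
            pa, pb = paths[a], paths[b]
            shared = 0
            for x, y in zip(pa, pb):
                if x is y:
                    shared += 1
                else:
                    break
            d = sum(n.length for n in pa[shared:]) + \
                sum(n.length for n in pb[shared:])
            out[(a, b)] = d
    return out


def test_jc_distance_closed_form():
    assert jc_distance(0.0) == 0.0
    assert jc_distance(0.10) == pytest.approx(
        -0.75 * math.log(1 - 0.4 / 3))
    with pytest.raises(ValueError):
        jc_distance(0.80)


def test_distance_matrix_identical_taxa():
    aln = {"A": "ACGT" * 50, "B": "ACGT" * 50, "C": "ACGT" * 50}
    dm, taxa = build_distance_matrix(aln)
    assert np.allclose(dm, 0)


def test_distance_matrix_symmetry(rng):
    root = rng.choice(list("ACGT"), size=400)
    taxa = {}
    for i in range(4):
        seq = root.copy()
        hit = rng.random(400) < 0.15
        seq[hit] = rng.choice(list("ACGT"), size=int(hit.sum()))
        gaps = rng.random(400) < 0.05
        seq[gaps] = "-"
        taxa[f"t{i}"] = "".join(seq)
    dm, _ = build_distance_matrix(taxa)
    assert np.allclose(dm, dm.T)
    assert np.allclose(np.diag(dm), 0)


def test_too_few_shared_columns_rejected():
    aln = {"A": "AC" + "-" * 200, "B": "-" * 200 + "AC", "C": "A" * 202}
    with pytest.raises(ValueError, match="share only"):
        build_distance_matrix(aln)


def test_three_taxon_closed_form():
    dm = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
    tree = neighbor_joining(dm, ["A", "B", "C"])
    lengths = {c.name: c.length for c in tree.children}
    assert lengths["A"] == pytest.approx(0.05)
    assert lengths["B"] == pytest.approx(0.15)
    assert lengths["C"] == pytest.approx(0.25)


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
def test_additive_matrix_recovered_exactly(n_taxa, rng):
    """NJ on an additive matrix reproduces the generating tree's topology
    and path lengths."""
    # random caterpillar-ish binary tree with positive branch lengths
    leaves = [_node(chr(65 + i), float(rng.uniform(0.05, 0.5)))
              for i in range(n_taxa)]
    while len(leaves) > 3:
        a = leaves.pop(0)
        b = leaves.pop(0)
        leaves.append(_node(None, float(rng.uniform(0.05, 0.5)), [a, b]))
    tree = _node(None, 0.0, leaves)
    want = _tree_distances(tree)
    taxa = sorted({a for pair in want for a in pair})
    n = len(taxa)
    dm = np.zeros((n, n))
    for (a, b), d in want.items():
        i, j = taxa.index(a), taxa.index(b)
        dm[i, j] = dm[j, i] = d
    nj = neighbor_joining(dm, taxa)
    got = _tree_distances(nj)
    for pair, d in want.items():
        assert got[pair] == pytest.approx(d, abs=1e-9)
    assert bipartitions(nj) == bipartitions(tree)


def test_nj_matches_skbio_on_additive_matrix():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    dm = np.array([
        [0, 5, 9, 9, 8],
        [5, 0, 10, 10, 9],
        [9, 10, 0, 8, 7],
        [9, 10, 8, 0, 3],
        [8, 9, 7, 3, 0]], dtype=float)
    taxa = list("ABCDE")
    mine = neighbor_joining(dm, taxa)
    other = skbio_nj(DistanceMatrix(dm, taxa))
    mine_bp = {tuple(sorted(bp)) for bp in bipartitions(mine)}
    other_bp = set()
    for node in other.non_tips():
        names = frozenset(t.name for t in node.tips())
        if 1 < len(names) < len(taxa) - 1:
            comp = frozenset(taxa) - names
            side = min(names, comp, key=lambda s: (len(s), sorted(s)))
            other_bp.add(tuple(sorted(side)))
    assert mine_bp == other_bp


def test_star_distances_degenerate():
    dm = np.full((4, 4), 0.5)
    np.fill_diagonal(dm, 0.0)
    tree = neighbor_joining(dm, list("ABCD"))
    assert sorted(tree.leaf_names()) == list("ABCD")
    assert all(c.length >= 0 for c in tree.children)


def test_negative_branches_clamped(rng):
    # a non-additive matrix prone to negative NJ branch estimates
    dm = np.array([
        [0.0, 0.1, 0.11, 0.6],
        [0.1, 0.0, 0.105, 0.61],
        [0.11, 0.105, 0.0, 0.01],
        [0.6, 0.61, 0.01, 0.0]])
    tree = neighbor_joining(dm, list("ABCD"))

    def check(node):
        assert node.length >= 0
        for c in node.children:
            check(c)

    check(tree)


def test_bootstrap_deterministic_and_confident():
    tree = _node(None, 0.0, [
        _node("O", 0.5),
        _node(None, 0.15, [_node("A", 0.1), _node("B", 0.1)]),
        _node(None, 0.15, [_node("C", 0.1), _node("D", 0.1)]),
    ])
    aln = simulate_jc_alignment(tree, 4000, rng=3)
    t1, s1 = bootstrap_support(aln, n_reps=60, seed=9)
    t2, s2 = bootstrap_support(aln, n_reps=60, seed=9)
    assert s1 == s2
    assert all(v >= 80 for v in s1.values())
    assert t1.newick() == t2.newick()


def test_outgroup_rooting():
    tree = _node(None, 0.0, [
        _node("O", 0.6),
        _node(None, 0.1, [_node("A", 0.1), _node("B", 0.1)]),
        _node(None, 0.1, [_node("C", 0.1), _node("D", 0.1)]),
    ])
    aln = simulate_jc_alignment(tree, 3000, rng=4)
    nj_tree, _ = bootstrap_support(aln, n_reps=10, seed=0)
    rooted = root_at_outgroup(nj_tree, "O")
    assert len(rooted.children) == 2
    names = [sorted(c.leaf_names()) for c in rooted.children]
    assert ["O"] in names
    ingroup = [c for c in rooted.children if c.leaf_names() != ["O"]][0]
    assert sorted(ingroup.leaf_names()) == ["A", "B", "C", "D"]


def test_concatenated_alignment_invariants():
    blocks = ({"A": "ACGT", "B": "ACGA"}, {"A": "GG", "B": "GC"})
    aln = ConcatenatedAlignment(("A", "B"), blocks)
    assert aln.total_columns == 6
    assert aln.concatenated() == {"A": "ACGTGG", "B": "ACGAGC"}
    with pytest.raises(ValueError, match="every taxon"):
        ConcatenatedAlignment(("A", "B"), ({"A": "ACGT"},))
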