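"""p-distances, neighbor joining, Newick round trips, rooting, clades."""

import itertools

import dendropy
import numpy as np
import pytest

from asca.msa import Alignment
from asca.phylo import (
    DistanceMatrix,
    extract_clades,
    leaf_labels,
    neighbor_joining,
    p_distance_matrix,
    parse_newick,
    read_newick,
    root_with_outgroup,
    to_newick,
    write_newick,
)
from asca.seqio import AMINO_ACIDS


def tree_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    return pdm.distance(tns.get_taxon(a), tns.get_taxon(b))


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as the smaller-or-either side leaf set."""
    leaves = frozenset(leaf_labels(tree))
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(leaves) - 1:
            out.add(min(below, frozenset(leaves - below), key=sorted))
    return out


# --- p-distances -----------------------------------------------------------

def test_p_distance_identical_rows_zero():
    aln = Alignment([("a", "MKLV"), ("b", "MKLV")])
    assert p_distance_matrix(aln).matrix[0, 1] == 0.0


def test_p_distance_direct_count():
    aln = Alignment([("a", "AAAA"), ("b", "AAAC")])
    assert p_distance_matrix(aln).matrix[0, 1] == pytest.approx(0.25)


def test_p_distance_no_comparable_columns_is_one():
    aln = Alignment([("a", "AA--"), ("b", "--AA")])
    assert p_distance_matrix(aln).matrix[0, 1] == 1.0


def test_p_distance_matches_column_scan_oracle():
    rng = np.random.default_rng(5)
    for _ in range(25):
        rows = []
        n_cols = int(rng.integers(5, 40))
        for i in range(4):
            chars = rng.choice(list(AMINO_ACIDS + "X"), size=n_cols)
            gaps = rng.random(n_cols) < 0.3
            rows.append((f"s{i}", "".join("-" if g else c for c, g in zip(chars, gaps))))
        aln = Alignment(rows)
        d = p_distance_matrix(aln).matrix
        for i, j in itertools.combinations(range(4), 2):
            ri, rj = rows[i][1], rows[j][1]
            comp = [
                (a, b)
                for a, b in zip(ri, rj)
                if a not in "-X" and b not in "-X"
            ]
            expected = (
                1.0
                if not comp
                else sum(a != b for a, b in comp) / len(comp)
            )
            assert d[i, j] == pytest.approx(expected)


# --- neighbor joining ------------------------------------------------------

def test_nj_requires_three_taxa():
    dm = DistanceMatrix(ids=("a", "b"), matrix=np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError, match="at least 3"):
        neighbor_joining(dm)


def test_nj_three_taxa_closed_form():
    m = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = neighbor_joining(DistanceMatrix(ids=("a", "b", "c"), matrix=m))
    # three-point formulas: la = (dab+dac-dbc)/2 etc.
    assert tree_distance(tree, "a", "b") == pytest.approx(3.0, abs=1e-9)
    assert tree_distance(tree, "a", "c") == pytest.approx(4.0, abs=1e-9)
    assert tree_distance(tree, "b", "c") == pytest.approx(5.0, abs=1e-9)


def test_nj_recovers_four_taxon_tree():
    """Additive distances from ((a:1,b:2):1,(c:3,d:4)) -> split {a,b}|{c,d}."""
    ids = ("a", "b", "c", "d")
    m = np.array(
        [
            [0.0, 3.0, 5.0, 6.0],
            [3.0, 0.0, 6.0, 7.0],
            [5.0, 6.0, 0.0, 7.0],
            [6.0, 7.0, 7.0, 0.0],
        ]
    )
    tree = neighbor_joining(DistanceMatrix(ids=ids, matrix=m))
    assert bipartitions(tree) == {frozenset({"a", "b"})}
    for x, y in itertools.combinations(ids, 2):
        assert tree_distance(tree, x, y) == pytest.approx(m[ids.index(x), ids.index(y)], abs=1e-9)


def random_additive_tree(rng, n_leaves):
    """Random binary topology with positive branch lengths, via dendropy."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    nodes = [f"t{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    tree = parse_newick(nodes[0] + ";")
    return tree, taxa


def test_nj_reproduces_random_additive_distances():
    rng = np.random.default_rng(23)
    for _ in range(10):
        n = int(rng.integers(4, 10))
        true_tree, taxa = random_additive_tree(rng, n)
        m = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            m[i, j] = m[j, i] = tree_distance(true_tree, taxa[i], taxa[j])
        nj = neighbor_joining(DistanceMatrix(ids=tuple(taxa), matrix=m))
        for i, j in itertools.combinations(range(n), 2):
            assert abs(tree_distance(nj, taxa[i], taxa[j]) - m[i, j]) < 1e-9
        assert bipartitions(nj) == bipartitions(true_tree)


def test_nj_topology_agrees_with_scikit_bio():
    """Independent oracle: skbio's neighbor joining on generic matrices."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(31)
    for _ in range(5):
        n = 7
        base = rng.uniform(0.2, 1.0, size=(n, n))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0.0)
        # make it tree-like enough to be unambiguous: distances from a tree
        true_tree, taxa = random_additive_tree(rng, n)
        for i, j in itertools.combinations(range(n), 2):
            m[i, j] = m[j, i] = tree_distance(true_tree, taxa[i], taxa[j])
        ours = neighbor_joining(DistanceMatrix(ids=tuple(taxa), matrix=m))
        theirs = skbio_nj(SkbioDM(m, ids=list(taxa)))
        assert bipartitions(ours) == bipartitions(parse_newick(str(theirs)))


def test_nj_agrees_with_upgma_on_ultrametric_distances():
    """On an ultrametric matrix the NJ topology equals the UPGMA topology
    (here derived independently via scipy average-linkage clustering)."""
    from scipy.cluster.hierarchy import average, to_tree
    from scipy.spatial.distance import squareform

    # ultrametric: a balanced 8-leaf clock tree
    newick = "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
    tree = parse_newick(newick)
    taxa = list("abcdefgh")
    n = len(taxa)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = tree_distance(tree, taxa[i], taxa[j])
    nj = neighbor_joining(DistanceMatrix(ids=tuple(taxa), matrix=m))

    link = average(squareform(m))
    root, _ = to_tree(link, rd=True)

    def splits_from_scipy(node, acc):
        if node.is_leaf():
            return {taxa[node.id]}
        below = splits_from_scipy(node.left, acc) | splits_from_scipy(node.right, acc)
        if 1 < len(below) < n - 1:
            acc.add(min(frozenset(below), frozenset(set(taxa) - below), key=sorted))
        return below

    acc: set[frozenset[str]] = set()
    splits_from_scipy(root, acc)
    assert bipartitions(nj) == acc


# --- Newick I/O ------------------------------------------------------------

def test_newick_two_leaf_round_trip(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("(a:1,b:2);\n")
    tree = read_newick(p)
    assert leaf_labels(tree) == {"a", "b"}


def test_newick_round_trip_50_leaves(tmp_path):
    rng = np.random.default_rng(9)
    tree, taxa = random_additive_tree(rng, 50)
    p = tmp_path / "big.nwk"
    write_newick(tree, p)
    back = read_newick(p)
    assert leaf_labels(back) == set(taxa)
    assert bipartitions(back) == bipartitions(tree)
    for a, b in [("t0", "t1"), ("t10", "t42"), ("t7", "t23")]:
        assert tree_distance(back, a, b) == pytest.approx(tree_distance(tree, a, b))
    # labels with underscores survive the round trip unquoted
    assert to_newick(back) == to_newick(tree)


def test_newick_unbalanced_parentheses(tmp_path):
    p = tmp_path / "bad.nwk"
    p.write_text("((a,b);")
    with pytest.raises(ValueError, match="offset"):
        read_newick(p)


# --- rooting ---------------------------------------------------------------

def test_root_on_single_outgroup_leaf():
    tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    rooted = root_with_outgroup(tree, ["d"])
    children = rooted.seed_node.child_nodes()
    sides = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in children]
    assert frozenset({"d"}) in sides
    assert frozenset({"a", "b", "c"}) in sides


def test_rooting_preserves_leaves_and_splits():
    tree = parse_newick("(((a:1,b:1):1,c:1):1,(d:1,e:1):2);")
    rooted = root_with_outgroup(tree, ["d", "e"])
    assert leaf_labels(rooted) == leaf_labels(tree)
    assert bipartitions(rooted) >= {frozenset({"a", "b"})}


def test_rooting_rejects_full_and_nonmonophyletic_outgroups():
    tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    with pytest.raises(ValueError, match="every leaf"):
        root_with_outgroup(tree, ["a", "b", "c", "d"])
    with pytest.raises(ValueError, match="not monophyletic"):
        root_with_outgroup(tree, ["a", "c"])
    with pytest.raises(ValueError, match="not in tree"):
        root_with_outgroup(tree, ["z"])


def test_rooting_recovers_simulated_ingroup(default_run):
    family, result = default_run
    tree = result.tree
    root_children = tree.seed_node.child_nodes()
    sides = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in root_children]
    assert frozenset(family.outgroup_ids) in sides
    ingroup_side = [s for s in sides if s != frozenset(family.outgroup_ids)]
    assert set().union(*ingroup_side) == set(family.ingroup_ids)


# --- clade extraction ------------------------------------------------------

def test_extract_k1_returns_whole_ingroup():
    tree = parse_newick("(((a:1,b:1):1,c:1):1,og:5);")
    rooted = root_with_outgroup(tree, ["og"])
    clades = extract_clades(rooted, k=1, outgroup_ids=["og"])
    assert clades == {"G1": {"a", "b", "c"}}


def test_extract_k2_cuts_the_long_branch():
    newick = "(((a:0.1,b:0.1):5,(c:0.1,d:0.1):0.2):1,og:5);"
    rooted = root_with_outgroup(parse_newick(newick), ["og"])
    clades = extract_clades(rooted, k=2, outgroup_ids=["og"])
    assert set(map(frozenset, clades.values())) == {
        frozenset({"a", "b"}),
        frozenset({"c", "d"}),
    }


def test_extract_clades_recovers_planted_partition(default_run):
    family, result = default_run
    truth = {}
    for sid in family.ingroup_ids:
        truth.setdefault(family.clade_of[sid], set()).add(sid)
    assert set(map(frozenset, result.clades.values())) == set(
        map(frozenset, truth.values())
    )
    # output is a partition of the ingroup
    union = set().union(*result.clades.values())
    assert union == set(family.ingroup_ids)
    assert sum(len(v) for v in result.clades.values()) == len(union)


def test_explicit_membership_modes():
    tree = parse_newick("(((a:1,b:1):1,(c:1,d:1):1):1,og:5);")
    rooted = root_with_outgroup(tree, ["og"])
    clades = extract_clades(
        rooted,
        membership={"a": "X", "b": "X", "c": "Y", "d": "Y"},
        outgroup_ids=["og"],
    )
    assert clades == {"X": {"a", "b"}, "Y": {"c", "d"}}
    with pytest.raises(ValueError, match="unknown leaves"):
        extract_clades(rooted, membership={"zz": "X"}, outgroup_ids=["og"])
    with pytest.warns(UserWarning, match="not monophyletic"):
        extract_clades(
            rooted,
            membership={"a": "X", "c": "X", "b": "Y", "d": "Y"},
            outgroup_ids=["og"],
        )
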