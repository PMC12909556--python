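"""Distance-based phylogeny: p-distances, neighbor joining, rooting, clades.

Trees are ``dendropy.Tree`` objects throughout.  Tree inference here is
deliberately light-weight — neighbor joining on p-distances — because the
downstream active-site analysis needs only a topology with branch lengths to
order and group the family; users with a maximum-likelihood tree from an
external program can import it as Newick and skip inference entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .msa import Alignment
from .seqio import GAP


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered id list."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "matrix", m)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                vals = "\t".join(f"{v:.6f}" for v in self.matrix[i])
                fh.write(f"{rid}\t{vals}\n")


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Proportion of mismatches over mutually comparable columns.

    A column is comparable for a pair when both rows carry a residue that is
    neither a gap nor X.  Pairs with no comparable column get distance 1.
    """
    if len(aln) < 2:
        raise ValueError("p-distances require at least 2 rows")
    ids = tuple(aln.ids)
    rows = [row for _, row in aln.rows]
    enc = np.array([[ord(c) for c in row] for row in rows], dtype=np.int16)
    opaque = (enc == ord(GAP)) | (enc == ord("X"))
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(opaque[i] | opaque[j])
            total = int(ok.sum())
            if total == 0:
                d[i, j] = d[j, i] = 1.0
            else:
                mism = int((enc[i, ok] != enc[j, ok]).sum())
                d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(ids=ids, matrix=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbor joining; exact on additive matrices.

    Ties in the Q criterion break on the smallest (i, j) node-index pair
    (indices in creation order), making the output deterministic.  Negative
    branch-length estimates are clamped to zero.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    taxa = dendropy.TaxonNamespace(list(dm.ids))
    nodes: dict[int, dendropy.Node] = {}
    for i, label in enumerate(dm.ids):
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[i] = node
    dist: dict[tuple[int, int], float] = {
        (i, j): float(dm.matrix[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    next_idx = n

    def d(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - sums[i] - sums[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        ci, cj = nodes.pop(i), nodes.pop(j)
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = max(0.0, li)
        cj.edge.length = max(0.0, lj)
        new_dists = {}
        for k in active:
            if k in (i, j):
                continue
            new_dists[k] = 0.5 * (d(i, k) + d(j, k) - dij)
        active = [k for k in active if k not in (i, j)]
        for k in active:
            a, b = (k, next_idx) if k < next_idx else (next_idx, k)
            dist[(a, b)] = max(0.0, new_dists[k])
        nodes[next_idx] = parent
        active.append(next_idx)
        next_idx += 1

    # final three-way join, closed form
    i, j, k = active
    center = dendropy.Node()
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    for idx, length in ((i, li), (j, lj), (k, lk)):
        child = nodes.pop(idx)
        center.add_child(child)
        child.edge.length = max(0.0, length)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(
                    f"unbalanced parenthesis at character offset {offset}"
                )
    if depth != 0:
        raise ValueError(
            f"unbalanced parentheses: {depth} unclosed at end of input "
            f"(offset {len(text)})"
        )


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick tree (underscores in labels preserved literally)."""
    text = Path(path).read_text()
    _check_parentheses(text)
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )


def parse_newick(text: str) -> dendropy.Tree:
    _check_parentheses(text)
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Rooting and clade extraction
# ---------------------------------------------------------------------------

def _leafset_below(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def root_with_outgroup(tree: dendropy.Tree, outgroup_ids: Sequence[str]) -> dendropy.Tree:
    """Root on the branch separating the outgroup from the ingroup.

    The outgroup must be non-empty, present, a proper subset of the leaves,
    and monophyletic with respect to the unrooted topology.  The root is
    placed at the midpoint of the separating branch.
    """
    outgroup = frozenset(outgroup_ids)
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    tree = tree.clone(depth=1)
    all_leaves = frozenset(leaf_labels(tree))
    missing = outgroup - all_leaves
    if missing:
        raise ValueError(f"outgroup ids not in tree: {sorted(missing)}")
    if outgroup == all_leaves:
        raise ValueError("outgroup cannot contain every leaf")

    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = _leafset_below(node)
        if below == outgroup or (all_leaves - below) == outgroup:
            target = node
            break
    if target is None:
        # report the smallest clade containing the outgroup
        tree.is_rooted = True  # mrca needs a rooted view
        mrca = tree.mrca(taxon_labels=sorted(outgroup))
        spanned = sorted(_leafset_below(mrca))
        raise ValueError(
            "outgroup is not monophyletic: the smallest containing clade is "
            f"{spanned} (bipartition conflict)"
        )
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    return tree


def extract_clades(
    tree: dendropy.Tree,
    k: int | None = None,
    membership: Mapping[str, str] | None = None,
    outgroup_ids: Sequence[str] = (),
) -> dict[str, set[str]]:
    """Partition the ingroup leaves into clades.

    Automatic mode (``k``): cut the k-1 longest internal ingroup branches of
    the rooted tree; the resulting components are the clades, labelled
    G1..Gk in order of their smallest leaf label.  Explicit mode
    (``membership``): a leaf -> label mapping covering the whole ingroup;
    non-monophyletic groups are warned about but accepted.
    """
    outgroup = frozenset(outgroup_ids)
    all_leaves = frozenset(leaf_labels(tree))
    ingroup = all_leaves - outgroup

    if membership is not None:
        unknown = set(membership) - all_leaves
        if unknown:
            raise ValueError(f"membership names unknown leaves: {sorted(unknown)}")
        uncovered = ingroup - set(membership)
        if uncovered:
            raise ValueError(
                f"membership does not cover ingroup leaves: {sorted(uncovered)}"
            )
        clades: dict[str, set[str]] = {}
        for leaf, label in membership.items():
            if leaf in ingroup:
                clades.setdefault(label, set()).add(leaf)
        for label, members in sorted(clades.items()):
            if not _is_monophyletic(tree, members, outgroup):
                warnings.warn(
                    f"clade {label!r} is not monophyletic in the rooted tree",
                    stacklevel=2,
                )
        return clades

    if k is None or k < 1:
        raise ValueError("provide k >= 1 or an explicit membership")
    # candidate cuts: internal edges whose subtree is a proper non-trivial
    # subset of the ingroup
    candidates = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = _leafset_below(node)
        if below <= ingroup and 1 < len(below) < len(ingroup):
            length = node.edge.length or 0.0
            candidates.append((length, sorted(below), node))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    if len(candidates) < k - 1:
        raise ValueError(
            f"cannot cut {k - 1} internal ingroup branches; only "
            f"{len(candidates)} available"
        )
    cut_nodes = [node for _, _, node in candidates[: k - 1]]
    cut_sets = [_leafset_below(node) for node in cut_nodes]
    groups: list[set[str]] = []
    for idx, below in enumerate(cut_sets):
        members = set(below)
        for jdx, other in enumerate(cut_sets):
            if jdx != idx and other < below:
                members -= other
        groups.append(members)
    remainder = set(ingroup) - set().union(*cut_sets) if cut_sets else set(ingroup)
    if remainder:
        groups.append(remainder)
    groups = [g for g in groups if g]
    groups.sort(key=lambda g: min(g))
    return {f"G{i + 1}": g for i, g in enumerate(groups)}


def _is_monophyletic(
    tree: dendropy.Tree, members: set[str], outgroup: frozenset[str]
) -> bool:
    mrca = tree.mrca(taxon_labels=sorted(members))
    if mrca is None:
        return False
    return _leafset_below(mrca) - outgroup == members
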