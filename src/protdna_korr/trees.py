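"""Minimal phylogenetic trees: neighbor joining, midpoint rooting, pruning.

Trees here exist to drive Gerstein-Sonnhammer-Chothia sequence weighting,
so the representation is deliberately small: nodes with a branch length to
their parent, leaves labelled by sequence id.  Newick import/export goes
through dendropy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

_EPS = 1e-12


class DistanceMatrixError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise DistanceMatrixError(f"shape {d.shape} does not match {n} ids")
        if not np.allclose(d, d.T, atol=1e-9):
            raise DistanceMatrixError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-9):
            raise DistanceMatrixError("distance matrix diagonal is not zero")
        if np.any(d < -1e-12):
            raise DistanceMatrixError("negative distances")
        self.values = d


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent; root carries 0
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted (or arbitrarily-rooted unrooted) tree over labelled leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [lf.name for lf in self.leaves()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")

    # -- traversal ---------------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def postorder_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(n: TreeNode) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    # -- distances ---------------------------------------------------------

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Patristic leaf-to-leaf distances (sum of branch lengths)."""
        leaves = self.leaves()
        n = len(leaves)
        out = np.zeros((n, n))
        updist: list[dict[int, float]] = []
        for lf in leaves:
            d: dict[int, float] = {}
            acc = 0.0
            node: TreeNode | None = lf
            while node is not None:
                d[id(node)] = acc
                acc += node.length
                node = node.parent
            updist.append(d)
        for a in range(n):
            for b in range(a + 1, n):
                da, db = updist[a], updist[b]
                best = min(da[k] + db[k] for k in da.keys() & db.keys())
                out[a, b] = out[b, a] = best
        return DistanceMatrix([lf.name for lf in leaves], out)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = n.name or ""
            return f"({inner}){label}:{n.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner}){self.root.name or ''};"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick")

        def convert(dn) -> TreeNode:
            node = TreeNode(
                name=dn.taxon.label if dn.taxon else None,
                length=float(dn.edge.length or 0.0),
            )
            for c in dn.child_nodes():
                node.add(convert(c))
            return node

        return cls(convert(dt.seed_node))

    def copy(self) -> "PhyloTree":
        def dup(n: TreeNode) -> TreeNode:
            m = TreeNode(n.name, n.length)
            for c in n.children:
                m.add(dup(c))
            return m

        return PhyloTree(dup(self.root))


# ---------------------------------------------------------------------------
# neighbor joining


def build_nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining, deterministic for a given input order.

    Ties in the Q criterion are broken by the lowest (i, j) index pair and
    negative branch-length estimates are clamped to zero, so repeated runs
    are bit-identical.  The returned tree is unrooted, represented with a
    trifurcation at the arbitrary root (or a single split for 2 taxa).
    """
    n = len(dm.ids)
    if n < 2:
        raise DistanceMatrixError("need at least 2 taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    if n == 2:
        # single edge bisected by the formal root
        half = dm.values[0, 1] / 2.0
        root = TreeNode()
        for node in nodes:
            node.length = max(half, 0.0)
            root.add(node)
        return PhyloTree(root)

    d = dm.values.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q = np.triu(q) + np.tril(np.full_like(q, np.inf))
        # lowest-index (ai, bi) among near-tied minima, for determinism
        qmin = q.min()
        cand = np.argwhere(q <= qmin + _EPS)
        ai, bi = min((int(a), int(b)) for a, b in cand)
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        u = TreeNode()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        u.add(nodes[i])
        u.add(nodes[j])
        # distances from the new node to the rest
        newrow = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(newrow) - 1] = newrow[:-1]
        d[: len(newrow) - 1, -1] = newrow[:-1]
        nodes.append(u)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # three-point formulas
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.add(nodes[idx])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# midpoint rooting


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the exact middle of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smaller (sorted) leaf-name pair.  When the midpoint coincides with an
    existing node, the tree is re-rooted at that node; otherwise the
    containing edge is subdivided.
    """
    tree = tree.copy()
    leaves = tree.leaves()
    if len(leaves) < 2:
        return tree
    dm = tree.leaf_distance_matrix()
    name_to_leaf = {lf.name: lf for lf in leaves}
    best = None
    for a, b in itertools.combinations(range(len(dm.ids)), 2):
        pair = tuple(sorted((dm.ids[a], dm.ids[b])))
        key = (-dm.values[a, b], pair)
        if best is None or key < best[0]:
            best = (key, pair, dm.values[a, b])
    _, (na, nb), total = best
    u, v = name_to_leaf[na], name_to_leaf[nb]
    path = _path_between(u, v)
    target = total / 2.0
    # walk from u toward v accumulating edge lengths
    acc = 0.0
    for a, b, ln in _path_edges(path):
        if acc + ln >= target - _EPS:
            x = target - acc  # distance from node a into this edge
            return _reroot_on_edge(tree, a, b, x, ln)
        acc += ln
    return _reroot_at_node(tree, path[-1])


def _path_between(u: TreeNode, v: TreeNode) -> list[TreeNode]:
    up: list[TreeNode] = []
    node: TreeNode | None = u
    while node is not None:
        up.append(node)
        node = node.parent
    seen = {id(n): k for k, n in enumerate(up)}
    down: list[TreeNode] = []
    node = v
    while id(node) not in seen:
        down.append(node)
        node = node.parent
    return up[: seen[id(node)] + 1] + list(reversed(down))


def _path_edges(path: list[TreeNode]):
    """Yield (near_node, far_node, length) along the path; edge length is the
    child's branch length regardless of orientation."""
    for a, b in zip(path, path[1:]):
        child = b if b.parent is a else a
        yield a, b, child.length


def _detach(child: TreeNode) -> None:
    child.parent.children.remove(child)
    child.parent = None


def _reverse_up(node: TreeNode) -> None:
    """Re-orient the tree so that ``node`` (already detached downward) absorbs
    its former parent as a child, recursively toward the old root."""
    parent = node.parent
    if parent is None:
        return
    _detach(node)
    _reverse_up(parent)
    parent.length = node.length
    node.length = 0.0
    node.add(parent)
    _prune_unary(parent)


def _prune_unary(node: TreeNode) -> None:
    """Splice out a degree-2 internal node left behind by re-rooting."""
    if node.is_leaf or len(node.children) != 1 or node.parent is None:
        return
    child = node.children[0]
    child.length += node.length
    parent = node.parent
    idx = parent.children.index(node)
    node.children = []
    child.parent = parent
    parent.children[idx] = child


def _reroot_at_node(tree: PhyloTree, node: TreeNode) -> PhyloTree:
    if node.parent is None:
        return tree
    _reverse_up(node)
    node.length = 0.0
    return PhyloTree(node)


def _reroot_on_edge(tree: PhyloTree, a: TreeNode, b: TreeNode, x: float, ln: float) -> PhyloTree:
    """New root at distance ``x`` from ``a`` on the a--b edge of length ``ln``."""
    if x <= _EPS:
        return _reroot_at_node(tree, a)
    if x >= ln - _EPS:
        return _reroot_at_node(tree, b)
    child = b if b.parent is a else a  # the lower endpoint in current rooting
    upper = a if child is b else b
    root = TreeNode()
    _detach(child)
    _reverse_up(upper)
    child.length = x if child is a else ln - x
    upper.length = ln - child.length
    root.add(child)
    root.add(upper)
    _prune_unary(child)
    _prune_unary(upper)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# pruning near-identical leaves


def prune_similar_leaves(
    tree: PhyloTree, threshold: float = 0.02, order: list[str] | None = None
) -> tuple[PhyloTree, list[str]]:
    """Greedily keep one representative per cluster of near-identical leaves.

    Leaves are visited in ``order`` (default: current leaf order); a leaf
    survives iff its patristic distance to every already-kept leaf is >=
    ``threshold``.  Mirrors collapsing redundant strains before weighting.
    """
    dm = tree.leaf_distance_matrix()
    idx = {name: k for k, name in enumerate(dm.ids)}
    names = order if order is not None else dm.ids
    kept: list[str] = []
    for name in names:
        if all(dm.values[idx[name], idx[k]] >= threshold for k in kept):
            kept.append(name)
    pruned = tree.copy()
    keep = set(kept)
    for lf in list(pruned.leaves()):
        if lf.name not in keep:
            _remove_leaf(pruned, lf)
    return pruned, kept


def _remove_leaf(tree: PhyloTree, leaf: TreeNode) -> None:
    parent = leaf.parent
    if parent is None:
        raise ValueError("cannot remove the last leaf")
    parent.children.remove(leaf)
    leaf.parent = None
    if len(parent.children) == 1 and parent.parent is not None:
        _prune_unary(parent)
    elif len(parent.children) == 1 and parent.parent is None:
        # root became unary: promote the single child to root
        child = parent.children[0]
        child.length = 0.0
        child.parent = None
        tree.root = child
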