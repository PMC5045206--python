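"""Sequence weighting: identity distances, GSC weights, pair weights.

Closely related sequences carry redundant evidence; the
Gerstein-Sonnhammer-Chothia (GSC) scheme down-weights them by distributing
branch lengths of a rooted tree among descendant leaves.  TF and site
weights are combined multiplicatively into per-pair weights, w(rs) =
w(r) x w(s), which every weighted count downstream uses.
"""

from __future__ import annotations

import numpy as np

from .alignments import GAP, PairedAlignmentSet
from .trees import DistanceMatrix, PhyloTree, build_nj_tree, midpoint_root


def sequence_distance_matrix(ids: list[str], rows: list[str]) -> DistanceMatrix:
    """Fractional identity distance with pairwise gap deletion.

    d(x, y) = 1 - matches / comparable, counting only columns where neither
    row has a gap; rows with no comparable columns get d = 1.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(r) for r in rows])
    gap = arr == GAP
    n = len(rows)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ok = ~(gap[a] | gap[b])
            comp = int(ok.sum())
            if comp == 0:
                dist = 1.0
            else:
                dist = 1.0 - float((arr[a, ok] == arr[b, ok]).sum()) / comp
            d[a, b] = d[b, a] = dist
    return DistanceMatrix(list(ids), d)


def gsc_weights(tree: PhyloTree) -> dict[str, float]:
    """Gerstein-Sonnhammer-Chothia leaf weights on a rooted tree.

    Each leaf starts with its own branch length; walking internal nodes
    leaf-up, each internal edge's length is divided among the leaves below
    it in proportion to their current weights (equal split when all are
    zero).  Weights are normalized to sum to the number of leaves, so the
    weighted sequence count N stays commensurate with the raw count.
    """
    weights: dict[int, float] = {}
    leaves_below: dict[int, list] = {}
    for node in tree.postorder_nodes():
        if node.is_leaf:
            weights[id(node)] = node.length
            leaves_below[id(node)] = [node]
        else:
            below = [lf for c in node.children for lf in leaves_below[id(c)]]
            leaves_below[id(node)] = below
            if node.parent is None:
                continue
            total = sum(weights[id(lf)] for lf in below)
            if total <= 0:
                share = node.length / len(below)
                for lf in below:
                    weights[id(lf)] += share
            else:
                for lf in below:
                    weights[id(lf)] += node.length * weights[id(lf)] / total

    leaves = tree.leaves()
    raw = np.array([weights[id(lf)] for lf in leaves])
    if raw.sum() <= 0:
        norm = np.ones(len(leaves))
    else:
        norm = raw * (len(leaves) / raw.sum())
    return {lf.name: float(w) for lf, w in zip(leaves, norm)}


def weights_from_alignment(ids: list[str], rows: list[str]) -> dict[str, float]:
    """Distance matrix -> NJ -> midpoint root -> GSC, the full weighting chain."""
    if len(ids) == 1:
        return {ids[0]: 1.0}
    dm = sequence_distance_matrix(ids, rows)
    tree = midpoint_root(build_nj_tree(dm))
    return gsc_weights(tree)


def uniform_weights(ids: list[str]) -> dict[str, float]:
    return {i: 1.0 for i in ids}


def weights_from_tree(tree: PhyloTree, ids: list[str]) -> dict[str, float]:
    """GSC weights from a user-supplied tree (bypasses internal NJ).

    The tree is midpoint-rooted first; its leaves must cover every id in
    ``ids`` (extra leaves are allowed and ignored in coverage checking but
    do influence the weighting, as they legitimately share branches).
    """
    missing = set(ids) - set(tree.leaf_names())
    if missing:
        raise KeyError(f"tree lacks leaves for ids: {sorted(missing)[:5]} ...")
    w = gsc_weights(midpoint_root(tree))
    return {i: w[i] for i in ids}


def assign_pair_weights(
    pset: PairedAlignmentSet,
    tf_weights: dict[str, float],
    site_weights: dict[str, float],
) -> PairedAlignmentSet:
    """Set w(rs) = w(r) x w(s) on every record; N = sum of pair weights."""
    return pset.with_weights(tf_weights, site_weights)


def weight_paired_set(
    pset: PairedAlignmentSet,
    site_mode: str = "gsc",
    tf_mode: str = "gsc",
    tf_tree: PhyloTree | None = None,
    site_tree: PhyloTree | None = None,
) -> PairedAlignmentSet:
    """Compute TF and site weights from the alignments and apply them.

    ``site_mode``/``tf_mode`` are "gsc" or "uniform".  Weights are computed
    over the distinct sequences appearing in the set (a TF paired with many
    sites contributes once to the TF tree).  A supplied tree replaces the
    internal distance-matrix/NJ construction for that side.
    """
    tf_ids, tf_rows, site_ids, site_rows = [], [], [], []
    seen_tf, seen_site = set(), set()
    for r in pset.records:
        if r.tf_id not in seen_tf:
            seen_tf.add(r.tf_id)
            tf_ids.append(r.tf_id)
            tf_rows.append(r.tf_row)
        if r.site_id not in seen_site:
            seen_site.add(r.site_id)
            site_ids.append(r.site_id)
            site_rows.append(r.site_row)

    def compute(mode, ids, rows, tree):
        if tree is not None:
            return weights_from_tree(tree, ids)
        if mode == "uniform":
            return uniform_weights(ids)
        if mode == "gsc":
            return weights_from_alignment(ids, rows)
        raise ValueError(f"unknown weighting mode {mode!r}")

    return assign_pair_weights(
        pset,
        compute(tf_mode, tf_ids, tf_rows, tf_tree),
        compute(site_mode, site_ids, site_rows, site_tree),
    )
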