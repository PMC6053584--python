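"""Neighbor-joining phylogeny, bootstrap supports, rooting and clock dating.

Trees are dendropy objects serialized as newick.  NJ follows Saitou & Nei
with deterministic tie-breaking (the candidate pair whose sorted cluster
labels are lexicographically smallest wins) and negative branch lengths
clamped to zero with the deficit re-added to the sister branch, so that
identical input always yields an identical newick string.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .alignment import SequenceAlignment
from .distance import DistanceMatrix, difference_matrix


def _new_tree(taxa: list[str]) -> dendropy.TaxonNamespace:
    return dendropy.TaxonNamespace(taxa)


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating seed node)."""
    if dist.n < 3:
        raise ValueError("need at least three items")
    tns = _new_tree(list(dist.ids))
    nodes: list[dendropy.Node] = []
    labels: list[str] = []
    for name in dist.ids:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(node)
        labels.append(name)
    d = dist.values.astype(float).copy()
    active = list(range(len(nodes)))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((labels[active[i]], labels[active[j]]))), i, j)
            for i, j in cands
            if i < j
        )
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        # clamp negatives, re-adding the deficit to the sister branch
        if vi < 0:
            vj += -vi
            vi = 0.0
        if vj < 0:
            vi += -vj
            vj = 0.0
        parent = dendropy.Node()
        na, nb = nodes[ai], nodes[aj]
        na.edge.length = float(vi)
        nb.edge.length = float(vj)
        parent.add_child(na)
        parent.add_child(nb)
        new_idx = len(nodes)
        nodes.append(parent)
        labels.append(min(labels[ai], labels[aj]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k_pos, ak in enumerate(active):
            if ak in (ai, aj):
                continue
            dk = 0.5 * (sub[i, k_pos] + sub[j, k_pos] - dij)
            d[new_idx, ak] = d[ak, new_idx] = max(dk, 0.0)
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    a, b = active
    if nodes[a].is_leaf() and not nodes[b].is_leaf():
        a, b = b, a
    # attach the remaining pair: final edge length split is arbitrary for an
    # unrooted tree; hang one under the other to obtain a trifurcation
    dab = max(d[a, b], 0.0)
    root = nodes[a]
    other = nodes[b]
    other.edge.length = float(dab)
    root.add_child(other)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as leafset frozensets, normalized to the side
    not containing the lexicographically first taxon."""
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = taxa[0]
    all_taxa = frozenset(taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


@dataclass
class _PatternMatrices:
    """Column-pattern compression for fast bootstrap distance matrices."""

    mismatch: np.ndarray  # (n_patterns, n, n) 0/1 mismatch indicators
    col_pattern: np.ndarray  # original column -> pattern index


def _compress_patterns(aln: SequenceAlignment) -> _PatternMatrices:
    from .distance import _encode

    codes, valid = _encode(aln)
    cols = np.ascontiguousarray(codes.T)
    view = cols.view([("", cols.dtype)] * cols.shape[1]).ravel()
    _, first_idx, inverse = np.unique(view, return_index=True, return_inverse=True)
    reps = codes[:, first_idx]
    vreps = valid[:, first_idx]
    n = codes.shape[0]
    n_pat = reps.shape[1]
    mm = np.zeros((n_pat, n, n), dtype=np.float32)
    for p in range(n_pat):
        c = reps[:, p]
        v = vreps[:, p]
        diff = (c[:, None] != c[None, :]) & v[:, None] & v[None, :]
        mm[p] = diff
    return _PatternMatrices(mm, inverse)


def bootstrap_support(
    aln: SequenceAlignment, n_reps: int = 10_000, seed: int | None = None
) -> dendropy.Tree:
    """NJ tree with internal-edge bootstrap supports (% of replicates).

    Columns are resampled with replacement; each replicate's NJ tree is
    scored for the bipartitions of the original tree.
    """
    if aln.n < 4:
        raise ValueError("need at least four sequences")
    base_dist = difference_matrix(aln)
    tree = nj_tree(base_dist)
    target = _bipartitions(tree)
    counts = {b: 0 for b in target}
    pats = _compress_patterns(aln)
    n_cols = len(pats.col_pattern)
    n_pat = pats.mismatch.shape[0]
    rng = np.random.default_rng(seed)
    ids = list(aln.sample_ids)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, n_cols)
        w = np.bincount(pats.col_pattern[cols], minlength=n_pat).astype(np.float32)
        mat = np.tensordot(w, pats.mismatch, axes=1).astype(float)
        np.fill_diagonal(mat, 0.0)
        rep_tree = nj_tree(DistanceMatrix(ids, (mat + mat.T) / 2))
        rep_bips = _bipartitions(rep_tree)
        for b in target:
            if b in rep_bips:
                counts[b] += 1
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = taxa[0]
    all_taxa = frozenset(taxa)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if side in counts:
            node.label = f"{100.0 * counts[side] / n_reps:.1f}"
            node.annotations["support"] = 100.0 * counts[side] / n_reps
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root on the midpoint of the outgroup's pendant edge."""
    rooted = tree.clone(depth=1)
    leaf = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup_id:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_id!r} not in tree")
    edge_len = leaf.edge.length or 0.0
    rooted.reroot_at_edge(leaf.edge, length1=edge_len / 2, length2=edge_len / 2)
    rooted.is_rooted = True
    return rooted


def unroot(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.deroot()
    t.is_rooted = False
    return t


def clock_node_ages(
    rooted_tree: dendropy.Tree,
    calibration_age_years: float,
    outgroup_id: str | None = None,
) -> tuple[dendropy.Tree, pd.DataFrame, float]:
    """Strict-clock node ages from per-site branch lengths.

    rate = (mean root-to-tip path) / calibration age; each node's age is its
    mean path length to descendant tips divided by that rate, clamped so
    ages never increase from root to tips.  Returns the annotated tree, a
    node-age table, and the ingroup coalescent age (MRCA of non-outgroup
    tips; the root age if no outgroup is named).
    """
    tree = rooted_tree.clone(depth=1)
    root = tree.seed_node
    # mean distance to descendant tips, bottom-up
    mean_depth: dict[dendropy.Node, tuple[float, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mean_depth[node] = (0.0, 1)
        else:
            tot, cnt = 0.0, 0
            for ch in node.child_nodes():
                m, c = mean_depth[ch]
                tot += c * (m + (ch.edge.length or 0.0))
                cnt += c
            mean_depth[node] = (tot / cnt, cnt)
    root_depth = mean_depth[root][0]
    if root_depth <= 0:
        raise ValueError("tree has zero depth; cannot calibrate")
    rate = root_depth / calibration_age_years
    rows = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.age = 0.0
            continue
        age = mean_depth[node][0] / rate
        if node.parent_node is not None:
            # mean-path depths need not be monotone; clamp to the parent age
            age = min(age, node.parent_node.age)
        node.age = age
        rows.append(
            {
                "node": node.label or "",
                "n_tips": mean_depth[node][1],
                "age_years": age,
            }
        )
    if outgroup_id is not None:
        ingroup = [
            lf.taxon for lf in tree.leaf_node_iter()
            if lf.taxon.label != outgroup_id
        ]
        mrca = tree.mrca(taxa=ingroup)
        ingroup_age = mrca.age
    else:
        ingroup_age = root.age
    table = pd.DataFrame(rows)
    return tree, table, float(ingroup_age)
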