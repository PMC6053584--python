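"""Spatial analysis of molecular variance (SAMOVA).

Searches over geographically contiguous groupings of populations for the
K-partition maximizing the among-group variance component Phi_CT, by
simulated annealing over a neighbor graph (Delaunay adjacency of the
population coordinates).  The best grouping over independent annealing runs
is reported with a permutation p-value for its Phi_CT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError

from .distance import DistanceMatrix
from .popmap import PopulationAssignment
from .structure import _ThreeLevelCalculator, _index_lists


def build_neighbor_graph(coordinates) -> nx.Graph:
    """Delaunay-derived adjacency on locally projected (lat, lon) points.

    Fewer than four populations give a complete graph; collinear points
    degrade to a path graph along the line.  Duplicate coordinates are
    jittered deterministically (warned).
    """
    pops = list(coordinates["population"])
    lat = np.asarray(coordinates["lat"], dtype=float)
    lon = np.asarray(coordinates["lon"], dtype=float)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    # local equirectangular projection: km east/north of the centroid
    lat0 = float(np.mean(lat))
    x = np.radians(lon) * math.cos(math.radians(lat0)) * 6371.0
    y = np.radians(lat) * 6371.0
    pts = np.column_stack([x, y])
    seen: dict[tuple, int] = {}
    for i in range(len(pops)):
        key = (round(pts[i, 0], 6), round(pts[i, 1], 6))
        if key in seen:
            import warnings

            warnings.warn("duplicate coordinates jittered", stacklevel=2)
            pts[i] += 1e-3 * (1 + seen[key])
            seen[key] += 1
        else:
            seen[key] = 0
    g = nx.Graph()
    g.add_nodes_from(pops)
    if len(pops) < 4:
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                g.add_edge(pops[i], pops[j])
        return g
    try:
        tri = Delaunay(pts)
    except QhullError:
        # collinear: connect nearest neighbors along the principal axis
        centered = pts - pts.mean(axis=0)
        axis = np.linalg.svd(centered, full_matrices=False)[2][0]
        order = np.argsort(centered @ axis)
        for a, b in zip(order[:-1], order[1:]):
            g.add_edge(pops[a], pops[b])
        return g
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                g.add_edge(pops[simplex[a]], pops[simplex[b]])
    return g


@dataclass
class SamovaResult:
    K: int
    grouping: dict[str, str]  # population -> group label
    phi_ct: float
    p_value: float | None
    n_runs: int
    n_steps: int
    seed: int | None
    trace: list[dict] = field(default_factory=list)


def _random_contiguous_partition(graph, K, rng) -> dict[str, int]:
    """Region-growing: K random seeds, then random frontier accretion."""
    nodes = list(graph.nodes)
    seeds = rng.choice(len(nodes), size=K, replace=False)
    label = {nodes[s]: g for g, s in enumerate(seeds)}
    frontier = [n for n in nodes if n not in label]
    while frontier:
        progressed = False
        rng.shuffle(frontier)
        for n in list(frontier):
            neigh = [label[m] for m in graph.neighbors(n) if m in label]
            if neigh:
                label[n] = neigh[int(rng.integers(len(neigh)))]
                frontier.remove(n)
                progressed = True
        if not progressed:  # disconnected graph: attach arbitrarily
            n = frontier.pop()
            label[n] = int(rng.integers(K))
    return label


def _group_pops(label: dict[str, int]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for p, g in label.items():
        out.setdefault(f"G{g + 1}", []).append(p)
    return out


def _contiguous(graph, members) -> bool:
    if len(members) <= 1:
        return True
    sub = graph.subgraph(members)
    return nx.is_connected(sub)


def samova_search(
    dist: DistanceMatrix,
    assignment: PopulationAssignment,
    coordinates,
    K: int,
    n_runs: int = 100,
    n_steps: int = 10_000,
    seed: int | None = None,
    n_perm: int = 1_000,
    spatial: bool = True,
    t0: float = 0.1,
    cooling: float = 0.9,
    cooling_every: int = 100,
) -> SamovaResult:
    """Best-of-``n_runs`` simulated annealing over contiguous K-partitions.

    Proposals move one border population into an adjacent group, keeping
    every group non-empty and (when ``spatial``) contiguous on the neighbor
    graph.  Improvements are always accepted; deteriorations with
    probability exp(delta/T) under geometric cooling.  With
    ``spatial=False`` the graph is complete and the search is unconstrained.
    """
    pops, idx = _index_lists(dist, assignment)
    if not 2 <= K <= len(pops):
        raise ValueError(f"K={K} outside [2, {len(pops)}]")
    if spatial:
        coords = coordinates[coordinates["population"].isin(pops)]
        graph = build_neighbor_graph(coords)
    else:
        graph = nx.complete_graph(pops)
    calc = _ThreeLevelCalculator(
        dist.values, idx, pops, {f"G{i + 1}": [p] for i, p in enumerate(pops[:2])}
    )

    def phi_ct(label):
        return calc.components(_group_pops(label))["phi_ct"]

    rng = np.random.default_rng(seed)
    best_label, best_phi = None, -np.inf
    trace = []
    for run in range(n_runs):
        label = _random_contiguous_partition(graph, K, rng)
        cur_phi = phi_ct(label)
        run_best_label, run_best_phi = dict(label), cur_phi
        temp = t0
        for step in range(n_steps):
            if step and step % cooling_every == 0:
                temp *= cooling
            # candidate border moves
            moves = []
            group_sizes: dict[int, int] = {}
            for g in label.values():
                group_sizes[g] = group_sizes.get(g, 0) + 1
            for p in pops:
                for q in graph.neighbors(p):
                    if label[q] != label[p] and group_sizes[label[p]] > 1:
                        moves.append((p, label[q]))
            if not moves:
                break
            p, new_g = moves[int(rng.integers(len(moves)))]
            old_g = label[p]
            if spatial:
                remaining = [m for m in pops if label[m] == old_g and m != p]
                if not _contiguous(graph, remaining):
                    continue
            label[p] = new_g
            new_phi = phi_ct(label)
            delta = new_phi - cur_phi
            if delta > 0 or rng.random() < math.exp(min(delta / max(temp, 1e-12), 0.0)):
                cur_phi = new_phi
                if cur_phi > run_best_phi:
                    run_best_phi, run_best_label = cur_phi, dict(label)
            else:
                label[p] = old_g
        trace.append({"run": run, "phi_ct": run_best_phi,
                      "grouping": _group_pops(run_best_label)})
        if run_best_phi > best_phi:
            best_phi, best_label = run_best_phi, dict(run_best_label)

    grouping = {p: f"G{g + 1}" for p, g in best_label.items()}
    # permutation p-value: populations shuffled among groups of fixed sizes
    p_value = None
    if n_perm > 0:
        gp = _group_pops(best_label)
        names = list(gp)
        sizes = [len(gp[g]) for g in names]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pops))
            shuffled, at = {}, 0
            for g, s in zip(names, sizes):
                shuffled[g] = [pops[i] for i in perm[at : at + s]]
                at += s
            if calc.components(shuffled)["phi_ct"] >= best_phi:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)
    return SamovaResult(
        K, grouping, float(best_phi), p_value, n_runs, n_steps, seed, trace
    )
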