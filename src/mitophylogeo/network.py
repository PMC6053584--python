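"""Statistical-parsimony haplotype networks.

Haplotypes are joined in order of increasing pairwise distance; each edge in
the resulting graph represents exactly one nucleotide change, with paths of
length > 1 filled by latent (unsampled) intermediate nodes.  Joins that
would exceed the connection limit -- the largest number of steps whose
parsimony probability (no hidden multiple hits) still meets the requested
confidence -- are refused, which can leave the network in several
components.

The parsimony probability of a j-step connection on an m-site sequence is
modeled as the probability that j mutations strike j distinct sites when
each mutation hits a site uniformly at random:

    P(j) = prod_{i=0..j-1} (1 - i/m),  with recursion P(j) = P(j-1)(1-(j-1)/m)

which is 1 for j <= 1 and decreases as hidden multiple hits become likely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment import HaplotypeTable


@dataclass
class ConnectionLimit:
    max_steps: int
    confidence: float
    seq_length: int


def parsimony_probability(j: int, seq_length: int) -> float:
    """P(no hidden multiple hits) for a j-step connection (direct product)."""
    if j < 0:
        raise ValueError("steps must be >= 0")
    p = 1.0
    for i in range(j):
        p *= 1.0 - i / seq_length
    return max(p, 0.0)


def connection_limit(seq_length: int, confidence: float = 0.90) -> ConnectionLimit:
    """Largest j with parsimony probability >= confidence, by recursion."""
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    p = 1.0
    j = 0
    while True:
        p_next = p * (1.0 - j / seq_length)  # P(j+1) from P(j)
        if p_next < confidence or p_next <= 0.0:
            break
        p = p_next
        j += 1
        if j > seq_length:
            break
    return ConnectionLimit(j, confidence, seq_length)


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # observed + latent nodes; every edge = one change
    observed: list[str]
    latent: list[str]
    components: list[set[str]] = field(default_factory=list)
    spanning_joins: list[tuple[str, str, int]] = field(default_factory=list)
    loops: list[tuple[str, str, int]] = field(default_factory=list)

    def n_samples(self) -> int:
        return sum(self.graph.nodes[h]["count"] for h in self.observed)

    def to_edge_list(self):
        return sorted(self.graph.edges())


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_network(
    haplotypes: HaplotypeTable,
    limit: ConnectionLimit,
    retain_loops: bool = True,
) -> HaplotypeNetwork:
    """Join haplotypes by increasing distance under the connection limit.

    Latent single-step nodes fill multi-step joins.  When a pair is already
    connected, a strictly shorter alternative route is always added; an
    equal-length alternative is recorded in ``loops`` and, with
    ``retain_loops``, kept as an explicit cycle when it is a direct
    single-step edge (multi-step alternatives would only duplicate the
    existing path through fresh latent nodes).  Ties in the join order are
    broken by total haplotype frequency, then lexicographic id.
    """
    hap_ids = sorted(haplotypes.haplotype_seq)
    excluded = haplotypes.excluded_positions
    if excluded:
        seqs = {
            h: "".join(c for i, c in enumerate(s, start=1) if i not in excluded)
            for h, s in haplotypes.haplotype_seq.items()
        }
    else:
        seqs = haplotypes.haplotype_seq
    totals = haplotypes.counts.sum(axis=1)
    g = nx.Graph()
    for h in hap_ids:
        pop_counts = (
            haplotypes.counts.loc[h].to_dict() if h in haplotypes.counts.index else {}
        )
        g.add_node(h, kind="observed", count=int(totals.get(h, 0)),
                   populations=pop_counts)
    pairs = sorted(
        (
            (_hamming(seqs[a], seqs[b]), -(totals.get(a, 0) + totals.get(b, 0)), a, b)
            for a, b in itertools.combinations(hap_ids, 2)
        )
    )
    latent: list[str] = []
    spanning: list[tuple[str, str, int]] = []
    loops: list[tuple[str, str, int]] = []

    def add_path(a: str, b: str, steps: int) -> None:
        prev = a
        for k in range(steps - 1):
            name = f"x{len(latent) + 1}"
            latent.append(name)
            g.add_node(name, kind="latent", count=0)
            g.add_edge(prev, name)
            prev = name
        g.add_edge(prev, b)

    for d, _, a, b in pairs:
        if d == 0 or d > limit.max_steps:
            continue
        if not nx.has_path(g, a, b):
            add_path(a, b, d)
            spanning.append((a, b, d))
            continue
        current = nx.shortest_path_length(g, a, b)
        if d < current:
            add_path(a, b, d)
        elif d == current:
            loops.append((a, b, d))
            if retain_loops and d == 1:
                add_path(a, b, d)
    comps = [set(c) for c in nx.connected_components(g)]
    return HaplotypeNetwork(g, hap_ids, latent, comps, spanning, loops)


def to_graphml(net: HaplotypeNetwork, path) -> None:
    g = net.graph.copy()
    for n in g.nodes:
        pops = g.nodes[n].pop("populations", None)
        if pops is not None:
            g.nodes[n]["populations"] = ";".join(
                f"{p}:{c}" for p, c in sorted(pops.items()) if c
            )
    nx.write_graphml(g, str(path))


def to_edge_tsv(net: HaplotypeNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in net.to_edge_list():
            fh.write(f"{a}\t{b}\n")


def to_dot(net: HaplotypeNetwork) -> str:
    lines = ["graph haplotype_network {"]
    for n, data in sorted(net.graph.nodes(data=True)):
        if data.get("kind") == "latent":
            lines.append(f'  "{n}" [shape=point];')
        else:
            lines.append(f'  "{n}" [label="{n} ({data.get("count", 0)})"];')
    for a, b in net.to_edge_list():
        lines.append(f'  "{a}" -- "{b}";')
    lines.append("}")
    return "\n".join(lines)
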