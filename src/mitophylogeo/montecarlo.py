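"""Monte Carlo randomization test of phylogeographic structure.

A discrete geographic character (four partitions of populations, states
1-4) is laid on the tips of a fixed tree; its minimum number of state
changes L is the unit-cost parsimony length.  The null distribution is
generated by permuting tip states uniformly among the included tips
(partition sizes fixed), and the tail statistic C% is the cumulative
percentage of randomized lengths less than or equal to the observed L
(the "L-inclusive tail").  A small C% means the observed geographic
distribution of clades is far more clustered than random dispersal.

Parsimony lengths use Hartigan's (1973) count-based generalization of the
Fitch downpass, which is exact for multifurcating trees with unit costs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .popmap import PopulationAssignment


@dataclass
class PartitionModel:
    """Four (or fewer) disjoint sets of populations defining tip states."""

    model_id: str
    partitions: dict[int, set[str]]  # state (1-based slot) -> populations

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pops in self.partitions.values():
            overlap = seen & set(pops)
            if overlap:
                raise ValueError(f"populations in two partitions: {sorted(overlap)}")
            seen |= set(pops)

    def state_of(self, population: str) -> int | None:
        for state, pops in self.partitions.items():
            if population in pops:
                return state
        return None

    @classmethod
    def from_tsv(cls, path, model_id: str | None = None) -> "PartitionModel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"population", "partition"} <= set(df.columns):
            raise ValueError("model TSV needs population and partition columns")
        parts: dict[int, set[str]] = {}
        for row in df.itertuples():
            parts.setdefault(int(row.partition), set()).add(row.population)
        return cls(model_id or str(path), parts)


@dataclass
class MonteCarloResult:
    model_id: str
    L_obs: int
    null_lengths: np.ndarray
    C_percent: float
    p_value: float
    n_rand: int
    n_tips: int
    seed: int | None = None
    stars: str = ""

    def summary_row(self) -> dict:
        return {
            "model": self.model_id,
            "n": self.n_tips,
            "L": self.L_obs,
            "C%": round(self.C_percent, 2),
            "significance": self.stars,
        }


class _TreeArrays:
    """Postorder traversal arrays for vectorized parsimony on a fixed tree."""

    def __init__(self, tree: dendropy.Tree, tip_labels: list[str]):
        label_set = set(tip_labels)
        work = tree.clone(depth=1)
        keep = [
            lf.taxon for lf in work.leaf_node_iter()
            if lf.taxon is not None and lf.taxon.label in label_set
        ]
        if len(keep) < len(label_set):
            missing = label_set - {t.label for t in keep}
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        n_leaves = sum(1 for _ in work.leaf_node_iter())
        if len(keep) < n_leaves:
            work.retain_taxa(keep)
        work.suppress_unifurcations()  # pruning can leave degree-2 nodes
        self.tip_index: dict[str, int] = {}
        nodes = list(work.postorder_node_iter())
        self.node_id = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.internal_order: list[int] = []
        self.tip_rows: list[int] = []
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                self.tip_index[nd.taxon.label] = i
                self.tip_rows.append(i)
            else:
                self.children[i] = [self.node_id[id(c)] for c in nd.child_nodes()]
                self.internal_order.append(i)
        self.tip_labels = sorted(self.tip_index, key=self.tip_index.get)


def _hartigan_lengths(arrays: _TreeArrays, states: np.ndarray, n_states: int):
    """Unit-cost parsimony length for each column of ``states``.

    ``states`` is (n_tips, n_cols) of 0-based states ordered to match
    ``arrays.tip_labels``.
    """
    n_cols = states.shape[1]
    member = np.zeros((arrays.n_nodes, n_cols, n_states), dtype=bool)
    for row, i in enumerate(arrays.tip_rows):
        member[i, np.arange(n_cols), states[row]] = True
    length = np.zeros(n_cols, dtype=np.int64)
    for i in arrays.internal_order:
        kids = arrays.children[i]
        counts = np.zeros((n_cols, n_states), dtype=np.int16)
        for c in kids:
            counts += member[c]
        kmax = counts.max(axis=1)
        member[i] = counts == kmax[:, None]
        length += len(kids) - kmax
    return length


def fitch_length(tree: dendropy.Tree, tip_states: dict[str, int]) -> int:
    """Minimum number of state changes of a tip character on a fixed tree.

    Tips absent from ``tip_states`` are pruned.  Exact for multifurcating
    trees (Hartigan downpass).
    """
    if not tip_states:
        raise ValueError("empty tip state map")
    labels = sorted(tip_states)
    arrays = _TreeArrays(tree, labels)
    uniq = sorted(set(tip_states.values()))
    code = {s: i for i, s in enumerate(uniq)}
    col = np.array(
        [[code[tip_states[lbl]]] for lbl in arrays.tip_labels], dtype=np.int64
    )
    return int(_hartigan_lengths(arrays, col, len(uniq))[0])


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"


def mc_phylogeo_test(
    tree: dendropy.Tree,
    assignment: PopulationAssignment,
    model: PartitionModel,
    n_rand: int = 10_000,
    seed: int | None = None,
) -> MonteCarloResult:
    """Observed parsimony length vs its tip-state-permutation null.

    Tips belonging to populations outside every partition are pruned before
    both the observed and the null lengths are computed.  C% counts null
    lengths <= L_obs (inclusive tail); stars follow the .05/.01/.001
    convention on C%/100.
    """
    if n_rand < 100:
        warnings.warn("n_rand < 100 gives a very coarse null", stacklevel=2)
    tip_states: dict[str, int] = {}
    for sample, pop in assignment.sample_to_population.items():
        state = model.state_of(pop)
        if state is not None:
            tip_states[sample] = state
    if not tip_states:
        raise ValueError("no tips covered by the model")
    states_present = sorted(set(tip_states.values()))
    labels = sorted(tip_states)
    arrays = _TreeArrays(tree, labels)
    code = {s: i for i, s in enumerate(states_present)}
    obs = np.array([code[tip_states[lbl]] for lbl in arrays.tip_labels])
    if len(states_present) == 1:
        return MonteCarloResult(model.model_id, 0, np.zeros(n_rand, dtype=int),
                                100.0, 1.0, n_rand, len(labels), seed, "ns")
    L_obs = int(_hartigan_lengths(arrays, obs[:, None], len(states_present))[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((len(obs), n_rand), dtype=np.int64)
    for k in range(n_rand):
        perms[:, k] = rng.permutation(obs)
    null = _hartigan_lengths(arrays, perms, len(states_present))
    c_percent = 100.0 * np.count_nonzero(null <= L_obs) / n_rand
    p = (np.count_nonzero(null <= L_obs) + 1) / (n_rand + 1)
    return MonteCarloResult(
        model.model_id, L_obs, null, float(c_percent), float(p),
        n_rand, len(labels), seed, _stars(p),
    )


def mc_table(results: list[MonteCarloResult]) -> pd.DataFrame:
    """Model/n/L/C% summary table across partition models."""
    return pd.DataFrame([r.summary_row() for r in results])
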