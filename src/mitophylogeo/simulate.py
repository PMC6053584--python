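"""Synthetic mitogenome datasets with known truth.

A structured-coalescent generator (msprime) emulating the data regime of a
whole-mitogenome phylogeography study: ~150 near-identical ~16.6-kb
sequences from ~14 sampling locations, transition-biased finite-sites
mutation, rare single-base indels, optional sudden demographic expansion,
and optional two-group splits with a known between-group divergence.

mtDNA is treated as a single non-recombining haploid locus; generations and
years are conflated 1:1 in simulation truth (calendar conversion belongs to
the clock/expansion modules).  Defaults mirror the study scale: 14
populations with sample sizes (7, 10, 18, 12, 14, 14, 10, 2, 11, 13, 11,
11, 10, 10), an island model whose expected Phi_ST is near 0.1, and a
transition:transversion ratio near 7.6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .alignment import SequenceAlignment, write_alignment
from .popmap import PopulationAssignment, write_population_map

#: Sample sizes of the 14 sampling locations in the emulated study design.
STUDY_SAMPLE_SIZES = (7, 10, 18, 12, 14, 14, 10, 2, 11, 13, 11, 11, 10, 10)


class ConfigurationError(ValueError):
    """Invalid demographic or mutational parameters."""


@dataclass
class SuddenExpansion:
    """Sudden-growth history in mismatch units: tau = 2 u t, theta = 2 N u."""

    tau: float
    theta0: float
    theta1: float

    def __post_init__(self) -> None:
        if self.tau < 0 or self.theta0 < 0 or self.theta1 <= 0:
            raise ConfigurationError("expansion parameters must be non-negative")
        if self.theta0 > self.theta1:
            raise ConfigurationError("theta0 must not exceed theta1")


@dataclass
class SimulationConfig:
    n_populations: int = 14
    samples_per_pop: tuple[int, ...] = STUDY_SAMPLE_SIZES
    seq_length: int = 16576
    per_site_mu: float = 2.3e-8  # substitutions/site/generation
    population_size: float = 3600.0  # haploid deme size (14 demes ~ theta 0.0023)
    migration_rate: float | None = 9.2e-5  # per deme pair; pairwise Phi_ST ~ 0.098
    split_time: float | None = None  # two-group split, generations ago
    group_labels: tuple[int, ...] | None = None  # 0/1 per population
    expansion: SuddenExpansion | None = None
    ts_tv_ratio: float = 7.6
    indel_rate: float = 1.5e-10  # per site per generation
    seed: int = 1
    population_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.samples_per_pop, int):
            self.samples_per_pop = (self.samples_per_pop,) * self.n_populations
        self.samples_per_pop = tuple(self.samples_per_pop)
        if self.n_populations < 1:
            raise ConfigurationError("need at least one population")
        if len(self.samples_per_pop) != self.n_populations:
            raise ConfigurationError("one sample size per population required")
        if any(s < 1 for s in self.samples_per_pop):
            raise ConfigurationError("sample sizes must be >= 1")
        if self.seq_length < 1:
            raise ConfigurationError("seq_length must be >= 1")
        for name, rate in (
            ("per_site_mu", self.per_site_mu),
            ("indel_rate", self.indel_rate),
        ):
            if rate < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.ts_tv_ratio < 0:
            raise ConfigurationError("ts_tv_ratio must be >= 0")
        if self.migration_rate is not None and self.migration_rate < 0:
            raise ConfigurationError("migration_rate must be >= 0")
        if (
            self.n_populations > 1
            and self.split_time is None
            and (self.migration_rate is None or self.migration_rate == 0)
        ):
            raise ConfigurationError(
                "multiple populations need migration or a split time"
            )
        if self.population_names is None:
            self.population_names = tuple(
                f"P{i + 1:02d}" for i in range(self.n_populations)
            )
        if len(self.population_names) != self.n_populations:
            raise ConfigurationError("one name per population required")
        if self.group_labels is not None and len(self.group_labels) != self.n_populations:
            raise ConfigurationError("one group label per population required")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_pop)

    @property
    def u_genome(self) -> float:
        """Per-lineage mutations per genome per generation."""
        return self.per_site_mu * self.seq_length

    def groups(self) -> tuple[int, ...]:
        if self.group_labels is not None:
            return tuple(self.group_labels)
        half = self.n_populations // 2
        return tuple(0 if i < half else 1 for i in range(self.n_populations))


@dataclass
class SyntheticTruth:
    phi_st: dict[str, float] = field(default_factory=dict)  # "A|B" -> value
    group_labels: dict[str, int] | None = None
    tau: float | None = None
    tmrca: float | None = None
    tree_newick: str | None = None
    partition_states: dict[str, int] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "phi_st": self.phi_st,
                "group_labels": self.group_labels,
                "tau": self.tau,
                "tmrca": self.tmrca,
                "tree_newick": self.tree_newick,
                "partition_states": self.partition_states,
            },
            indent=1,
        )


def _demography(config: SimulationConfig) -> msprime.Demography:
    demo = msprime.Demography()
    N = config.population_size
    names = config.population_names
    if config.expansion is not None:
        u = config.u_genome
        if u <= 0:
            raise ConfigurationError("expansion requires a positive mutation rate")
        t = config.expansion.tau / (2.0 * u)
        n1 = config.expansion.theta1 / (2.0 * u)
        n0 = max(config.expansion.theta0 / (2.0 * u), 1e-3)
        for name in names:
            demo.add_population(name=name, initial_size=n1)
        for name in names:
            demo.add_population_parameters_change(
                time=t, population=name, initial_size=n0
            )
    else:
        for name in names:
            demo.add_population(name=name, initial_size=N)
    if config.n_populations == 1:
        return demo
    groups = config.groups()
    m = config.migration_rate or 0.0
    if config.split_time is None:
        for i in range(config.n_populations):
            for j in range(config.n_populations):
                if i != j:
                    demo.set_migration_rate(names[i], names[j], m)
    else:
        for i in range(config.n_populations):
            for j in range(config.n_populations):
                if i != j and groups[i] == groups[j] and m > 0:
                    demo.set_migration_rate(names[i], names[j], m)
        demo.add_population(name="ANC", initial_size=N)
        demo.add_population_split(
            time=config.split_time, derived=list(names), ancestral="ANC"
        )
    return demo


def simulate_genealogy(config: SimulationConfig):
    """One coalescent genealogy over all samples; tips labelled by population.

    Returns the tskit TreeSequence (single non-recombining tree, branch
    lengths in generations) and the per-sample population names in sample
    order.
    """
    demo = _demography(config)
    samples = {
        name: n for name, n in zip(config.population_names, config.samples_per_pop)
    }
    try:
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demo,
            ploidy=1,
            sequence_length=config.seq_length,
            random_seed=(config.seed % (2**31 - 2)) + 1,
        )
    except (ValueError, msprime.InputError) as err:  # pragma: no cover
        raise ConfigurationError(str(err)) from err
    labels = []
    pop_names = {p.id: p.metadata["name"] for p in ts.populations()}
    for s in ts.samples():
        labels.append(pop_names[ts.node(s).population])
    return ts, labels


_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T in ACGT coding
_TRANSVERSIONS = {0: (1, 3), 2: (1, 3), 1: (0, 2), 3: (0, 2)}
_ALPHABET = np.frombuffer(b"ACGT-", dtype="S1")


def mutate_sequences(ts, config: SimulationConfig, labels=None) -> SequenceAlignment:
    """Finite-sites mutation with transition bias down the genealogy.

    Substitutions are Poisson on branches (rate per_site_mu * L per
    generation), each hitting a uniform site; a hit is a transition with
    probability ts_tv_ratio/(ts_tv_ratio+1).  Indels are independent
    Poisson events writing a gap character; gaps are absorbing.
    """
    if ts.num_trees != 1:
        raise ConfigurationError("expected a single non-recombining tree")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11E]))
    tree = ts.first()
    L = config.seq_length
    kappa = config.ts_tv_ratio
    p_ts = kappa / (kappa + 1.0) if kappa >= 0 else 0.5
    seqs: dict[int, np.ndarray] = {}
    roots = list(tree.roots)
    order: list[int] = []
    for root in roots:
        seqs[root] = rng.integers(0, 4, L, dtype=np.int8)
        order.extend(tree.nodes(root, order="preorder"))
    for node in order:
        parent = tree.parent(node)
        if parent == -1:
            continue
        seq = seqs[parent].copy()
        t = tree.branch_length(node)
        n_sub = rng.poisson(config.per_site_mu * L * t)
        for site in rng.integers(0, L, n_sub):
            cur = seq[site]
            if cur == 4:
                continue  # gaps are absorbing
            if rng.random() < p_ts:
                seq[site] = _TRANSITION[int(cur)]
            else:
                seq[site] = _TRANSVERSIONS[int(cur)][int(rng.integers(2))]
        n_indel = rng.poisson(config.indel_rate * L * t)
        if n_indel:
            seq[rng.integers(0, L, n_indel)] = 4
        seqs[node] = seq
        if tree.num_children(parent) and all(
            c in seqs for c in tree.children(parent)
        ):
            del seqs[parent]  # free internal sequences once all children done
    if labels is None:
        _, labels = _sample_labels(ts)
    sample_ids = make_sample_ids(labels)
    out = [
        "".join(np.char.decode(_ALPHABET[seqs[s]]))
        for s in ts.samples()
    ]
    return SequenceAlignment(sample_ids, out)


def _sample_labels(ts):
    pop_names = {p.id: p.metadata["name"] for p in ts.populations()}
    labels = [pop_names[ts.node(s).population] for s in ts.samples()]
    return ts.samples(), labels


def make_sample_ids(labels: list[str]) -> list[str]:
    counter: dict[str, int] = {}
    out = []
    for pop in labels:
        counter[pop] = counter.get(pop, 0) + 1
        out.append(f"{pop}_{counter[pop]:02d}")
    return out


def _synthetic_coordinates(config: SimulationConfig, rng) -> pd.DataFrame:
    """Populations on a North-Atlantic-like arc, grouped contiguously."""
    names = list(config.population_names)
    order = sorted(range(len(names)), key=lambda i: (config.groups()[i], i))
    lats, lons = {}, {}
    for rank, i in enumerate(order):
        frac = rank / max(len(names) - 1, 1)
        lats[names[i]] = 45.0 + 20.0 * frac + rng.normal(0, 0.3)
        lons[names[i]] = -60.0 + 80.0 * frac + rng.normal(0, 0.3)
    return pd.DataFrame(
        {
            "population": names,
            "lat": [round(lats[n], 4) for n in names],
            "lon": [round(lons[n], 4) for n in names],
        }
    )


def _pair_coalescence_times(config: SimulationConfig) -> np.ndarray:
    """Exact E[pairwise coalescence time] for every deme pair.

    Solves the two-lineage structured-coalescent Markov chain (states are
    unordered deme pairs, absorption = coalescence) by linear algebra; for
    the split model the within-group phase is integrated over [0, T_split]
    with a matrix exponential and the ancestral phase adds its mean.
    """
    from scipy.linalg import expm

    d = config.n_populations
    N = config.population_size
    m = config.migration_rate or 0.0
    groups = config.groups()
    same_group = np.array(
        [[groups[i] == groups[j] for j in range(d)] for i in range(d)]
    )
    # backward migration rates between demes, mirroring _demography
    mig = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            if i != j and (config.split_time is None or same_group[i, j]):
                mig[i, j] = m
    states = [(i, j) for i in range(d) for j in range(i, d)]
    pos = {s: k for k, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    for (i, j), k in pos.items():
        for lineage, other in ((i, j), (j, i)):
            for dest in range(d):
                rate = mig[lineage, dest]
                if rate > 0:
                    tgt = pos[tuple(sorted((dest, other)))]
                    Q[k, tgt] += rate
                    Q[k, k] -= rate
        if i == j:
            Q[k, k] -= 1.0 / N  # coalescence (absorbing outflow)
    ones = np.ones(n)
    if config.split_time is None:
        expected = np.linalg.solve(-Q, ones)
    else:
        T = config.split_time
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = Q
        aug[:n, n] = 1.0
        M = expm(aug * T)
        survive = M[:n, :n] @ ones
        expected = M[:n, n] + survive * N  # ancestral phase adds mean N
    out = np.zeros((d, d))
    for (i, j), k in pos.items():
        out[i, j] = out[j, i] = expected[k]
    return out


def _truth_phist(config: SimulationConfig) -> dict[str, float]:
    """Expected pairwise Phi_ST from mean coalescence times (Slatkin).

    Phi = (T_between - T_within) / T_between, with T the exact expectations
    under the generating demography -- independent of any simulated data.
    Not defined for time-varying sizes (expansion histories).
    """
    if config.n_populations < 2 or config.expansion is not None:
        return {}
    names = config.population_names
    T = _pair_coalescence_times(config)
    out = {}
    for i, a in enumerate(names):
        for j in range(i + 1, config.n_populations):
            t_b = T[i, j]
            t_w = 0.5 * (T[i, i] + T[j, j])
            out[f"{a}|{names[j]}"] = (t_b - t_w) / t_b if t_b > 0 else 0.0
    return out


def generate_dataset(
    config: SimulationConfig,
    outdir,
    compute_truth_phist: bool = True,
) -> dict:
    """Write FASTA + population TSV + coordinates TSV + truth JSON.

    Deterministic given the config seed (byte-identical artifacts).
    Returns the paths and the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ts, labels = simulate_genealogy(config)
    aln = mutate_sequences(ts, config, labels)
    assignment = PopulationAssignment(
        dict(zip(aln.sample_ids, labels)),
        {
            name: f"G{g + 1}"
            for name, g in zip(config.population_names, config.groups())
        }
        if (config.split_time is not None or config.group_labels is not None)
        else None,
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC00]))
    coords = _synthetic_coordinates(config, rng)
    tree = ts.first()
    truth = SyntheticTruth(
        phi_st=_truth_phist(config) if compute_truth_phist else {},
        group_labels=dict(zip(config.population_names, config.groups()))
        if config.n_populations > 1
        else None,
        tau=config.expansion.tau if config.expansion else None,
        tmrca=float(max(tree.time(r) for r in tree.roots)),
        tree_newick=tree.as_newick(),
        partition_states={
            sid: config.groups()[config.population_names.index(pop)] + 1
            for sid, pop in zip(aln.sample_ids, labels)
        }
        if config.n_populations > 1
        else None,
    )
    paths = {
        "alignment": outdir / "alignment.fasta",
        "populations": outdir / "populations.tsv",
        "coordinates": outdir / "coordinates.tsv",
        "truth": outdir / "truth.json",
    }
    write_alignment(aln, paths["alignment"])
    write_population_map(assignment, paths["populations"])
    coords.to_csv(paths["coordinates"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    return {
        "paths": paths,
        "alignment": aln,
        "assignment": assignment,
        "coordinates": coords,
        "truth": truth,
        "tree_sequence": ts,
    }


def generate_intensity_table(
    aln: SequenceAlignment,
    noise_sd: float,
    seed: int | None = None,
    sample_id: str | None = None,
    signal: float = 100.0,
    background: float = 10.0,
    discordant_positions: frozenset[int] = frozenset(),
) -> pd.DataFrame:
    """Four-channel intensities (both strands) for one sample's sequence.

    The true base's channel has mean ``signal``, others ``background``;
    Gaussian noise with ``noise_sd`` is added and clipped at zero, so the
    dS/N spread is controlled by ``noise_sd``.  Positions listed in
    ``discordant_positions`` (1-based) have the reverse strand's signal
    moved to a different channel, emulating a strand-discordant artifact.
    Gap positions are skipped.
    """
    rng = np.random.default_rng(seed)
    sid = sample_id or aln.sample_ids[0]
    seq = aln.sequences[aln.sample_ids.index(sid)]
    channel = {"A": 0, "C": 1, "G": 2, "T": 3}
    rows = []
    for pos, base in enumerate(seq, start=1):
        if base not in channel:
            continue
        for strand in ("forward", "reverse"):
            true = channel[base]
            if strand == "reverse" and pos in discordant_positions:
                true = (true + 1) % 4
            means = np.full(4, background)
            means[true] = signal
            vals = np.clip(means + rng.normal(0.0, noise_sd, 4), 0.0, None)
            rows.append(
                {
                    "position": pos,
                    "strand": strand,
                    "I_A": vals[0],
                    "I_C": vals[1],
                    "I_G": vals[2],
                    "I_T": vals[3],
                    "ref": base,
                }
            )
    return pd.DataFrame(rows)
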