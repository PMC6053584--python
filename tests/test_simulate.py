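"""Synthetic-data generator: determinism, genealogy, mutation model, truth."""

import itertools

import numpy as np
import pytest

from mitophylogeo.simulate import (
    ConfigurationError,
    SimulationConfig,
    SuddenExpansion,
    generate_dataset,
    mutate_sequences,
    simulate_genealogy,
)


def small_config(**kw):
    base = dict(
        n_populations=2, samples_per_pop=(4, 4), seq_length=1000,
        per_site_mu=1e-5, population_size=400, migration_rate=1e-3, seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_populations=0)
        with pytest.raises(ConfigurationError):
            small_config(samples_per_pop=(4, 0))
        with pytest.raises(ConfigurationError):
            small_config(seq_length=0)
        with pytest.raises(ConfigurationError):
            small_config(per_site_mu=-1e-9)

    def test_isolated_demes_without_split_rejected(self):
        with pytest.raises(ConfigurationError, match="migration"):
            small_config(migration_rate=0.0)

    def test_expansion_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            SuddenExpansion(tau=-1, theta0=0, theta1=10)
        with pytest.raises(ConfigurationError):
            SuddenExpansion(tau=5, theta0=20, theta1=10)


class TestGenealogy:
    def test_minimal_coalescent_single_pair(self):
        cfg = SimulationConfig(
            n_populations=1, samples_per_pop=(2,), seq_length=100,
            per_site_mu=0.0, population_size=100, migration_rate=None, seed=1,
        )
        ts, labels = simulate_genealogy(cfg)
        tree = ts.first()
        internal = [u for u in tree.nodes() if not tree.is_leaf(u)]
        assert len(internal) == 1
        assert labels == ["P01", "P01"]

    def test_old_split_gives_reciprocal_monophyly(self):
        # zero migration + very old split: first coalescences within demes
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = SimulationConfig(
                n_populations=2, samples_per_pop=(5, 5), seq_length=100,
                per_site_mu=0.0, population_size=100, migration_rate=0.0,
                split_time=100_000, seed=seed + 1,
            )
            ts, labels = simulate_genealogy(cfg)
            tree = ts.first()
            samples = list(ts.samples())
            left = [s for s, p in zip(samples, labels) if p == "P01"]
            mrca_left = left[0]
            for s in left[1:]:
                mrca_left = tree.mrca(mrca_left, s)
            leaves_under = set(tree.leaves(mrca_left))
            if leaves_under == set(left):
                hits += 1
        assert hits == n_rep  # split at 1000N: monophyly essentially certain

    def test_high_migration_mixes_labels_like_random_permutation(self, rng):
        """In the strong-migration limit the deme labelling on the tree is
        indistinguishable from a random relabelling: the parsimony length
        of the observed labelling sits inside the permutation null."""
        import dendropy

        from mitophylogeo.montecarlo import fitch_length

        cfg = SimulationConfig(
            n_populations=2, samples_per_pop=(10, 10), seq_length=100,
            per_site_mu=0.0, population_size=200, migration_rate=0.5, seed=42,
        )
        ts, labels = simulate_genealogy(cfg)
        tree = dendropy.Tree.get(data=ts.first().as_newick(), schema="newick")
        tips = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        states = {t: (0 if lab == "P01" else 1)
                  for t, lab in zip([f"n{s}" for s in ts.samples()], labels)}
        obs = fitch_length(tree, states)
        null = []
        vals = list(states.values())
        for _ in range(200):
            rng.shuffle(vals)
            null.append(fitch_length(tree, dict(zip(states, vals))))
        null = np.array(null)
        se = null.std() / np.sqrt(len(null))
        assert abs(obs - null.mean()) <= max(2 * null.std(), 4 * se)


class TestMutation:
    def test_zero_rate_identical_sequences(self):
        cfg = small_config(per_site_mu=0.0, indel_rate=0.0)
        ts, labels = simulate_genealogy(cfg)
        aln = mutate_sequences(ts, cfg, labels)
        assert len(set(aln.sequences)) == 1

    def test_pairwise_differences_match_branch_length_expectation(self):
        # E[diffs] ~ 2 * mu * L * E[pair coalescence time]; Monte Carlo mean
        # across replicates should sit within a few relative SE of it
        mu, L, N = 2e-6, 4000, 500
        diffs = []
        for seed in range(30):
            cfg = SimulationConfig(
                n_populations=1, samples_per_pop=(2,), seq_length=L,
                per_site_mu=mu, population_size=N, migration_rate=None,
                seed=seed + 1,
            )
            ts, labels = simulate_genealogy(cfg)
            aln = mutate_sequences(ts, cfg, labels)
            diffs.append(
                sum(a != b for a, b in zip(aln.sequences[0], aln.sequences[1]))
            )
        expect = 2 * mu * L * N
        assert np.mean(diffs) == pytest.approx(expect, rel=0.5)

    def test_transition_fraction_matches_ts_tv_ratio(self):
        # kappa = 8 -> P(transition) = 8/9, checked over >= 1000 changes
        cfg = SimulationConfig(
            n_populations=1, samples_per_pop=(40,), seq_length=50_000,
            per_site_mu=1e-5, population_size=800, migration_rate=None,
            ts_tv_ratio=8.0, indel_rate=0.0, seed=3,
        )
        ts, labels = simulate_genealogy(cfg)
        aln = mutate_sequences(ts, cfg, labels)
        from mitophylogeo.alignment import classify_sites

        sc = classify_sites(aln)
        n = sc.n_transitions + sc.n_transversions
        assert n >= 1000
        frac = sc.n_transitions / n
        p = 8 / 9
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 4 * se

    def test_indels_appear_as_single_base_gaps(self):
        cfg = small_config(indel_rate=5e-6)
        ts, labels = simulate_genealogy(cfg)
        aln = mutate_sequences(ts, cfg, labels)
        assert any("-" in s for s in aln.sequences)


class TestGenerateDataset:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = small_config()
        d1 = generate_dataset(cfg, tmp_path / "a")
        d2 = generate_dataset(cfg, tmp_path / "b")
        for key in ("alignment", "populations", "coordinates", "truth"):
            assert d1["paths"][key].read_bytes() == d2["paths"][key].read_bytes()

    def test_roundtrip_through_sequence_io(self, tmp_path):
        from mitophylogeo.alignment import read_alignment
        from mitophylogeo.popmap import read_population_map

        cfg = small_config()
        data = generate_dataset(cfg, tmp_path / "d")
        aln = read_alignment(data["paths"]["alignment"])
        assert aln.sequences == data["alignment"].sequences
        assignment = read_population_map(data["paths"]["populations"])
        assert assignment.sample_to_population == data[
            "assignment"
        ].sample_to_population

    def test_truth_phist_zero_when_panmictic(self, tmp_path):
        cfg = small_config(migration_rate=5.0)  # effectively one population
        data = generate_dataset(cfg, tmp_path / "p")
        truth = data["truth"].phi_st["P01|P02"]
        assert truth == pytest.approx(0.0, abs=5e-3)
        # and the downstream estimate is statistically consistent with zero
        from mitophylogeo.distance import difference_matrix
        from mitophylogeo.structure import amova

        res = amova(
            difference_matrix(data["alignment"]), data["assignment"],
            n_perm=200, seed=5,
        )
        assert res.p_values["phi_st"] > 0.05

    def test_phist_estimates_monotone_in_divergence_time(self, tmp_path):
        from mitophylogeo.distance import difference_matrix
        from mitophylogeo.structure import amova

        phis = []
        for split in (200, 2000, 20000):
            cfg = SimulationConfig(
                n_populations=2, samples_per_pop=(10, 10), seq_length=4000,
                per_site_mu=2e-6, population_size=800, migration_rate=0.0,
                split_time=split, seed=11,
            )
            data = generate_dataset(cfg, tmp_path / f"s{split}",
                                    compute_truth_phist=False)
            phis.append(
                amova(difference_matrix(data["alignment"]),
                      data["assignment"], n_perm=0).phi_st
            )
        assert phis[0] < phis[1] < phis[2]

    def test_study_scale_dataset_loads(self, tmp_path):
        import time

        t0 = time.time()
        data = generate_dataset(SimulationConfig(seed=2), tmp_path / "full",
                                compute_truth_phist=False)
        assert time.time() - t0 < 60
        aln = data["alignment"]
        assert aln.n == 153 and aln.length == 16576
        assert len(data["assignment"].populations) == 14
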