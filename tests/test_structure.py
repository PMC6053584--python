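"""AMOVA against a brute-force oracle, FDR, Mantel, PCoA, chi-square."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitophylogeo.distance import DistanceMatrix
from mitophylogeo.popmap import PopulationAssignment
from mitophylogeo.structure import (
    amova,
    by_stepup,
    contingency_chisq,
    fdr_critical,
    geographic_distance_matrix,
    great_circle_distance,
    mantel_ibd,
    pairwise_phist,
    pcoa,
)


def random_distance_matrix(rng, n, integer=True):
    m = rng.integers(0, 30, (n, n)).astype(float) if integer else rng.random((n, n))
    m = np.triu(m, 1)
    m = m + m.T
    return m


def oracle_two_level(D, blocks):
    """Explicit pairwise-loop AMOVA (Excoffier-Smouse-Quattro, 2 levels)."""
    N = sum(len(b) for b in blocks)
    P = len(blocks)
    everyone = [i for b in blocks for i in b]
    ss_total = sum(D[i, j] for i, j in itertools.combinations(everyone, 2)) / N
    ss_wp = sum(
        sum(D[i, j] for i, j in itertools.combinations(b, 2)) / len(b)
        for b in blocks
    )
    ss_ap = ss_total - ss_wp
    sigma_w = ss_wp / (N - P)
    n_c = (N - sum(len(b) ** 2 for b in blocks) / N) / (P - 1)
    sigma_a = (ss_ap / (P - 1) - sigma_w) / n_c
    return ss_ap, ss_wp, sigma_a, sigma_w, sigma_a / (sigma_a + sigma_w)


def oracle_three_level(D, group_blocks):
    """Explicit-loop 3-level AMOVA; group_blocks maps group -> list of blocks."""
    blocks = [b for bs in group_blocks.values() for b in bs]
    N = sum(len(b) for b in blocks)
    P = len(blocks)
    G = len(group_blocks)
    everyone = [i for b in blocks for i in b]
    ss_total = sum(D[i, j] for i, j in itertools.combinations(everyone, 2)) / N
    ss_wp = sum(
        sum(D[i, j] for i, j in itertools.combinations(b, 2)) / len(b)
        for b in blocks
    )
    ss_wg = 0.0
    s_over_ng = 0.0
    ng2 = 0.0
    for bs in group_blocks.values():
        members = [i for b in bs for i in b]
        Ng = len(members)
        ss_wg += sum(D[i, j] for i, j in itertools.combinations(members, 2)) / Ng
        s_over_ng += sum(len(b) ** 2 for b in bs) / Ng
        ng2 += Ng**2
    ss_ag = ss_total - ss_wg
    ss_ap_wg = ss_wg - ss_wp
    sigma_c = ss_wp / (N - P)
    n = (N - s_over_ng) / (P - G)
    sigma_b = (ss_ap_wg / (P - G) - sigma_c) / n
    n_pr = (s_over_ng - sum(len(b) ** 2 for b in blocks) / N) / (G - 1)
    n_dpr = (N - ng2 / N) / (G - 1)
    sigma_a = (ss_ag / (G - 1) - sigma_c - n_pr * sigma_b) / n_dpr
    tot = sigma_a + sigma_b + sigma_c
    return sigma_a, sigma_b, sigma_c, sigma_a / tot


def make_assignment(sizes, ids=None):
    s2p = {}
    k = 0
    for p, n in enumerate(sizes):
        for _ in range(n):
            s2p[f"s{k:02d}"] = f"P{p + 1}"
            k += 1
    return PopulationAssignment(s2p)


class TestAmova:
    def test_identical_populations_phi_near_zero(self, rng):
        # two populations with identical multisets of sequences
        base = random_distance_matrix(rng, 4)
        D = np.tile(base, (2, 2))
        np.fill_diagonal(D, 0)
        D = (D + D.T) / 2
        dist = DistanceMatrix([f"s{i:02d}" for i in range(8)], D)
        res = amova(dist, make_assignment([4, 4]), n_perm=200, seed=1)
        assert res.phi_st < 0.05
        assert res.p_values["phi_st"] > 0.3

    def test_fixed_haplotypes_phi_one(self):
        # each population fixed for its own haplotype: no within variance
        D = np.zeros((6, 6))
        D[:3, 3:] = 10
        D[3:, :3] = 10
        dist = DistanceMatrix([f"s{i:02d}" for i in range(6)], D)
        res = amova(dist, make_assignment([3, 3]), n_perm=0)
        assert res.phi_st == pytest.approx(1.0)

    def test_matches_brute_force_oracle_two_level(self, rng):
        for sizes in [(3, 4), (2, 3, 4), (4, 4, 2, 2), (5, 3, 4)]:
            n = sum(sizes)
            D = random_distance_matrix(rng, n)
            dist = DistanceMatrix([f"s{i:02d}" for i in range(n)], D)
            res = amova(dist, make_assignment(sizes), n_perm=0)
            blocks, k = [], 0
            for s in sizes:
                blocks.append(list(range(k, k + s)))
                k += s
            ss_ap, ss_wp, sa, sw, phi = oracle_two_level(D, blocks)
            assert res.sums_of_squares["among_populations"] == pytest.approx(ss_ap, abs=1e-10)
            assert res.sums_of_squares["within_populations"] == pytest.approx(ss_wp, abs=1e-10)
            assert res.variance_components["sigma_a"] == pytest.approx(sa, abs=1e-10)
            assert res.variance_components["sigma_w"] == pytest.approx(sw, abs=1e-10)
            assert res.phi_st == pytest.approx(phi, abs=1e-10)

    def test_matches_brute_force_oracle_three_level(self, rng):
        sizes = (3, 2, 3, 4)  # 12 samples, two groups of two populations
        n = sum(sizes)
        D = random_distance_matrix(rng, n)
        dist = DistanceMatrix([f"s{i:02d}" for i in range(n)], D)
        assignment = make_assignment(sizes)
        groups = {"P1": "A", "P2": "A", "P3": "B", "P4": "B"}
        res = amova(dist, assignment, groups=groups, n_perm=0)
        blocks, k = [], 0
        for s in sizes:
            blocks.append(list(range(k, k + s)))
            k += s
        sa, sb, sc, phi_ct = oracle_three_level(
            D, {"A": blocks[:2], "B": blocks[2:]}
        )
        assert res.variance_components["sigma_a"] == pytest.approx(sa, abs=1e-10)
        assert res.variance_components["sigma_b"] == pytest.approx(sb, abs=1e-10)
        assert res.variance_components["sigma_c"] == pytest.approx(sc, abs=1e-10)
        assert res.phi_ct == pytest.approx(phi_ct, abs=1e-10)

    def test_percent_variation_sums_to_100(self, rng):
        D = random_distance_matrix(rng, 10)
        dist = DistanceMatrix([f"s{i:02d}" for i in range(10)], D)
        res = amova(dist, make_assignment([5, 5]), n_perm=0)
        assert sum(res.percent_variation.values()) == pytest.approx(100.0)

    def test_unassigned_sample_rejected(self, rng):
        D = random_distance_matrix(rng, 4)
        dist = DistanceMatrix([f"s{i:02d}" for i in range(4)], D)
        bad = PopulationAssignment({"s00": "P1", "s01": "P1", "s02": "P2"})
        with pytest.raises(ValueError, match="unassigned"):
            amova(dist, bad)


class TestPairwisePhist:
    def test_symmetric_zero_diagonal_and_consistency(self, rng):
        sizes = (4, 4, 3)
        n = sum(sizes)
        D = random_distance_matrix(rng, n)
        dist = DistanceMatrix([f"s{i:02d}" for i in range(n)], D)
        assignment = make_assignment(sizes)
        pw = pairwise_phist(dist, assignment, n_perm=50, seed=2)
        assert np.allclose(pw.phi.to_numpy(), pw.phi.to_numpy().T)
        assert np.allclose(np.diag(pw.phi.to_numpy()), 0)
        # each cell equals a full 2-level AMOVA on that pair alone
        samples = assignment.samples_of("P1") + assignment.samples_of("P2")
        sub_assign = PopulationAssignment(
            {s: assignment.sample_to_population[s] for s in samples}
        )
        res = amova(dist.submatrix(samples), sub_assign, n_perm=0)
        assert pw.phi.loc["P1", "P2"] == pytest.approx(res.phi_st)

    def test_small_populations_excluded(self, rng):
        sizes = (4, 4, 2)
        n = sum(sizes)
        D = random_distance_matrix(rng, n)
        dist = DistanceMatrix([f"s{i:02d}" for i in range(n)], D)
        pw = pairwise_phist(dist, make_assignment(sizes), n_perm=10, seed=1)
        assert pw.excluded == ["P3"]
        assert pw.m == 1


class TestFdrCritical:
    def test_printed_critical_values(self):
        assert round(fdr_critical(0.05, 78), 4) == 0.0101
        assert round(fdr_critical(0.05, 36), 3) == 0.012

    def test_single_test_returns_alpha(self):
        assert fdr_critical(0.05, 1) == pytest.approx(0.05)

    def test_strictly_decreasing_in_m(self):
        vals = [fdr_critical(0.05, m) for m in range(1, 40)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_stepup_agrees_with_fixed_cut_for_flat_p(self):
        p = np.array([0.001, 0.5, 0.9])
        assert by_stepup(p, 0.05).tolist() == [True, False, False]


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_distance((47.5, -52.7), (47.5, -52.7)) == 0.0

    def test_quarter_meridian(self):
        # equator to pole = 2*pi*R/4 at R = 6371 km
        assert great_circle_distance((0, 0), (90, 0)) == pytest.approx(
            2 * np.pi * 6371 / 4, rel=1e-6
        )

    def test_symmetry(self):
        a, b = (60.1, 5.2), (44.6, -63.5)
        assert great_circle_distance(a, b) == great_circle_distance(b, a)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            great_circle_distance((95, 0), (0, 0))


class TestMantel:
    def test_perfect_correlation(self, rng):
        n = 7
        phi = random_distance_matrix(rng, n, integer=False) * 0.5
        geo_vals = 3.0 * (phi / (1 - phi))
        genetic = DistanceMatrix([f"P{i}" for i in range(n)], phi)
        geo = DistanceMatrix([f"P{i}" for i in range(n)], geo_vals)
        res = mantel_ibd(genetic, geo, n_perm=200, seed=5)
        assert res.r == pytest.approx(1.0)
        assert res.p < 0.05

    def test_constant_matrix_rejected(self):
        n = 5
        ids = [f"P{i}" for i in range(n)]
        const = np.ones((n, n)) * 0.2
        np.fill_diagonal(const, 0)
        geo = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        with pytest.raises(ValueError, match="degenerate"):
            mantel_ibd(DistanceMatrix(ids, const), DistanceMatrix(ids, geo),
                       n_perm=10, seed=1)

    def test_phi_one_cells_excluded(self, rng):
        n = 5
        ids = [f"P{i}" for i in range(n)]
        phi = random_distance_matrix(rng, n, integer=False) * 0.5
        phi[0, 1] = phi[1, 0] = 1.0
        geo = random_distance_matrix(rng, n, integer=False)
        with pytest.warns(UserWarning, match="excluded"):
            res = mantel_ibd(DistanceMatrix(ids, phi), DistanceMatrix(ids, geo),
                             n_perm=20, seed=1)
        assert res.n_pairs == n * (n - 1) // 2 - 1


class TestPcoa:
    def test_points_on_a_line(self):
        n = 6
        D = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float) * 2.5
        res = pcoa(DistanceMatrix([f"i{i}" for i in range(n)], D))
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_zero_matrix_gives_zero_coordinates(self):
        res = pcoa(DistanceMatrix(["a", "b", "c"], np.zeros((3, 3))))
        assert res.coordinates.to_numpy().size == 0 or np.allclose(
            res.coordinates.to_numpy(), 0
        )

    def test_planar_configuration_recovered(self, rng):
        from scipy.spatial import procrustes
        from scipy.spatial.distance import squareform, pdist

        pts = rng.random((8, 2)) * 10
        D = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"i{i}" for i in range(8)], D), n_axes=2)
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_percent_variance_non_increasing(self, rng):
        D = random_distance_matrix(rng, 9, integer=False)
        res = pcoa(DistanceMatrix([f"i{i}" for i in range(9)], D))
        pv = res.percent_variance
        assert all(a >= b - 1e-12 for a, b in zip(pv, pv[1:]))

    def test_matches_skbio_percent_variance(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.random((7, 3))
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(pts))
        ours = pcoa(DistanceMatrix([f"i{i}" for i in range(7)], D))
        theirs = skbio_pcoa(skbio.DistanceMatrix(D, [f"i{i}" for i in range(7)]))
        k = len(ours.percent_variance)
        np.testing.assert_allclose(
            ours.percent_variance,
            100 * theirs.proportion_explained.to_numpy()[:k],
            atol=1e-6,
        )


class TestChiSquare:
    def test_independence_gives_zero(self):
        tab = np.outer([10, 20], [5, 15]) / 50
        chi2, df, p = contingency_chisq(tab)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        chi2, df, p = contingency_chisq([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_zero_margins_dropped(self):
        tab = [[5, 0, 5], [3, 0, 7], [0, 0, 0]]
        with pytest.warns(UserWarning, match="zero-margin"):
            chi2, df, p = contingency_chisq(tab)
        assert df == 1  # 2x2 after dropping


def test_geographic_matrix_from_coordinates():
    coords = pd.DataFrame(
        {"population": ["a", "b"], "lat": [0.0, 0.0], "lon": [0.0, 90.0]}
    )
    gm = geographic_distance_matrix(coords)
    assert gm.values[0, 1] == pytest.approx(2 * np.pi * 6371 / 4, rel=1e-6)
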