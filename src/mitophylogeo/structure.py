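"""AMOVA variance decomposition and related population-structure inference.

The analysis of molecular variance (Excoffier, Smouse & Quattro) decomposes
pairwise-distance variance hierarchically.  For mtDNA the squared distance
between two haplotypes is taken to be their absolute number of nucleotide
differences.  Phi statistics are ratios of variance components:

    2-level:  Phi_ST = sigma_a / (sigma_a + sigma_w)
    3-level:  Phi_CT = sigma_a / total,  Phi_SC = sigma_b / (sigma_b + sigma_c),
              Phi_ST = (sigma_a + sigma_b) / total

Permutation p-values use the (b+1)/(B+1) convention.  Null schemes follow
the standard AMOVA permutational design: individuals among populations for
Phi_ST, individuals among populations within groups for Phi_SC, and whole
populations among groups for Phi_CT.

Also here: the modified false-discovery-rate critical value
p_crit = alpha / sum_{i=1..m} 1/i (Benjamini-Yekutieli), Mantel tests of
isolation by distance on linearized Phi/(1-Phi), classical-scaling PCoA,
great-circle distances, and Pearson contingency chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distance import DistanceMatrix
from .popmap import PopulationAssignment

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    levels: int  # 2 or 3
    df: dict[str, int]
    sums_of_squares: dict[str, float]
    variance_components: dict[str, float]
    percent_variation: dict[str, float]
    phi_st: float
    phi_ct: float | None = None
    phi_sc: float | None = None
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None


def _index_lists(dist: DistanceMatrix, assignment: PopulationAssignment):
    index = {s: i for i, s in enumerate(dist.ids)}
    unassigned = [s for s in dist.ids if s not in assignment.sample_to_population]
    if unassigned:
        raise ValueError(f"unassigned samples: {unassigned}")
    pops = [p for p in assignment.populations if assignment.samples_of(p)]
    idx = {p: np.array([index[s] for s in assignment.samples_of(p)
                        if s in index], dtype=int) for p in pops}
    idx = {p: v for p, v in idx.items() if len(v) > 0}
    for p, v in idx.items():
        if len(v) == 1:
            warnings.warn(f"population {p!r} has a single sample", stacklevel=3)
    return list(idx), idx


def _ss_within(D2: np.ndarray, blocks: list[np.ndarray]) -> float:
    return sum(D2[np.ix_(b, b)].sum() / (2.0 * len(b)) for b in blocks)


def _two_level_components(ss_total, ss_wp, n_sizes, N):
    P = len(n_sizes)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, N - P
    sigma_w = ss_wp / df_wp
    n_c = (N - np.sum(np.square(n_sizes)) / N) / df_ap
    sigma_a = (ss_ap / df_ap - sigma_w) / n_c
    return ss_ap, sigma_a, sigma_w


def amova(
    dist: DistanceMatrix,
    assignment: PopulationAssignment,
    groups: dict[str, str] | None = None,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on a matrix of pairwise nucleotide differences.

    ``groups`` maps population -> group for the 3-level design; without it a
    2-level (among/within population) decomposition is returned.  Set
    ``n_perm=0`` to skip permutation p-values.
    """
    pops, idx = _index_lists(dist, assignment)
    D2 = dist.values  # differences enter as the squared metric
    N = dist.n
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    ss_total = D2.sum() / (2.0 * N)
    blocks = [idx[p] for p in pops]
    n_sizes = np.array([len(b) for b in blocks], dtype=float)
    ss_wp = _ss_within(D2, blocks)
    rng = np.random.default_rng(seed)

    if groups is None:
        ss_ap, sigma_a, sigma_w = _two_level_components(ss_total, ss_wp, n_sizes, N)
        total = sigma_a + sigma_w
        phi_st = sigma_a / total
        p_values = {}
        if n_perm > 0:
            hits = 0
            pool = np.concatenate(blocks)
            sizes = [len(b) for b in blocks]
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                new_blocks, at = [], 0
                for s in sizes:
                    new_blocks.append(perm[at : at + s])
                    at += s
                ss_wp_p = _ss_within(D2, new_blocks)
                _, sa, sw = _two_level_components(ss_total, ss_wp_p, n_sizes, N)
                if sa / (sa + sw) >= phi_st:
                    hits += 1
            p_values["phi_st"] = (hits + 1) / (n_perm + 1)
        return AmovaResult(
            levels=2,
            df={"among_populations": len(pops) - 1, "within_populations": N - len(pops)},
            sums_of_squares={
                "among_populations": ss_ap,
                "within_populations": ss_wp,
                "total": ss_total,
            },
            variance_components={"sigma_a": sigma_a, "sigma_w": sigma_w},
            percent_variation={
                "among_populations": 100.0 * sigma_a / total,
                "within_populations": 100.0 * sigma_w / total,
            },
            phi_st=float(phi_st),
            p_values=p_values,
            n_permutations=n_perm,
            seed=seed,
        )

    # --- 3-level design -----------------------------------------------------
    missing = [p for p in pops if p not in groups]
    if missing:
        raise ValueError(f"populations without group: {missing}")
    group_names = sorted({groups[p] for p in pops})
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    group_pops = {g: [p for p in pops if groups[p] == g] for g in group_names}
    calc = _ThreeLevelCalculator(D2, idx, pops, group_pops)
    res = calc.components()
    p_values = {}
    if n_perm > 0:
        p_values = calc.permutation_pvalues(res, n_perm, rng)
    sigma_a, sigma_b, sigma_c = res["sigma_a"], res["sigma_b"], res["sigma_c"]
    total = sigma_a + sigma_b + sigma_c
    return AmovaResult(
        levels=3,
        df=res["df"],
        sums_of_squares=res["ss"],
        variance_components={
            "sigma_a": sigma_a, "sigma_b": sigma_b, "sigma_c": sigma_c,
        },
        percent_variation={
            "among_groups": 100.0 * sigma_a / total,
            "among_populations_within_groups": 100.0 * sigma_b / total,
            "within_populations": 100.0 * sigma_c / total,
        },
        phi_st=float(res["phi_st"]),
        phi_ct=float(res["phi_ct"]),
        phi_sc=float(res["phi_sc"]),
        p_values=p_values,
        n_permutations=n_perm,
        seed=seed,
    )


class _ThreeLevelCalculator:
    """3-level AMOVA with population-pair sums precomputed.

    Keeping the population x population matrix of summed squared distances
    makes each regrouping O(P^2), which the SAMOVA annealer relies on.
    """

    def __init__(self, D2, idx, pops, group_pops):
        self.D2 = D2
        self.pops = list(pops)
        self.idx = idx
        self.group_pops = {g: list(ps) for g, ps in group_pops.items()}
        self.n_p = np.array([len(idx[p]) for p in pops], dtype=float)
        self.N = int(self.n_p.sum())
        P = len(pops)
        T = np.zeros((P, P))
        for a in range(P):
            for b in range(a, P):
                s = D2[np.ix_(idx[pops[a]], idx[pops[b]])].sum()
                T[a, b] = T[b, a] = s
        self.T = T  # full double-counted sums; within-pop pairs = T[p,p]/2
        self.ss_total = D2.sum() / (2.0 * self.N)
        self.ss_wp = float(np.sum(np.diag(T) / (2.0 * self.n_p)))
        self.pop_pos = {p: i for i, p in enumerate(pops)}

    def components(self, group_pops=None):
        gp = self.group_pops if group_pops is None else group_pops
        pops, n_p, N, T = self.pops, self.n_p, self.N, self.T
        P, G = len(pops), len(gp)
        if P - G <= 0:
            # every population its own group: no within-group population level
            pass
        ss_wg = 0.0
        S_over_Ng = 0.0
        Ng2 = 0.0
        for ps in gp.values():
            ii = np.array([self.pop_pos[p] for p in ps], dtype=int)
            Ng = n_p[ii].sum()
            ss_wg += T[np.ix_(ii, ii)].sum() / (2.0 * Ng)
            S_over_Ng += np.sum(n_p[ii] ** 2) / Ng
            Ng2 += Ng**2
        ss_ag = self.ss_total - ss_wg
        ss_ap_wg = ss_wg - self.ss_wp
        df_ag, df_ap, df_wp = G - 1, P - G, N - P
        sigma_c = self.ss_wp / df_wp
        if df_ap > 0:
            n = (N - S_over_Ng) / df_ap
            sigma_b = (ss_ap_wg / df_ap - sigma_c) / n
        else:
            sigma_b = 0.0
        n_pr = (S_over_Ng - np.sum(n_p**2) / N) / df_ag
        n_dpr = (N - Ng2 / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n_pr * sigma_b) / n_dpr
        total = sigma_a + sigma_b + sigma_c
        return {
            "df": {
                "among_groups": df_ag,
                "among_populations_within_groups": df_ap,
                "within_populations": df_wp,
            },
            "ss": {
                "among_groups": ss_ag,
                "among_populations_within_groups": ss_ap_wg,
                "within_populations": self.ss_wp,
                "total": self.ss_total,
            },
            "sigma_a": sigma_a,
            "sigma_b": sigma_b,
            "sigma_c": sigma_c,
            "phi_ct": sigma_a / total,
            "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else 0.0,
            "phi_st": (sigma_a + sigma_b) / total,
        }

    def permutation_pvalues(self, observed, n_perm, rng):
        pops = self.pops
        group_names = list(self.group_pops)
        group_sizes = [len(self.group_pops[g]) for g in group_names]
        hits_ct = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pops))
            gp, at = {}, 0
            for g, s in zip(group_names, group_sizes):
                gp[g] = [pops[i] for i in perm[at : at + s]]
                at += s
            if self.components(gp)["phi_ct"] >= observed["phi_ct"]:
                hits_ct += 1
        # individual-level permutations for Phi_SC (within groups) and Phi_ST
        hits_sc = hits_st = 0
        pop_sizes = {p: len(self.idx[p]) for p in pops}
        for _ in range(n_perm):
            idx_sc: dict[str, np.ndarray] = {}
            for ps in self.group_pops.values():
                pool = np.concatenate([self.idx[p] for p in ps])
                perm = rng.permutation(pool)
                at = 0
                for p in ps:
                    idx_sc[p] = perm[at : at + pop_sizes[p]]
                    at += pop_sizes[p]
            calc = _ThreeLevelCalculator(
                self.D2, idx_sc, pops, self.group_pops
            )
            if calc.components()["phi_sc"] >= observed["phi_sc"]:
                hits_sc += 1
            pool = np.concatenate([self.idx[p] for p in pops])
            perm = rng.permutation(pool)
            idx_st, at = {}, 0
            for p in pops:
                idx_st[p] = perm[at : at + pop_sizes[p]]
                at += pop_sizes[p]
            calc = _ThreeLevelCalculator(self.D2, idx_st, pops, self.group_pops)
            if calc.components()["phi_st"] >= observed["phi_st"]:
                hits_st += 1
        return {
            "phi_ct": (hits_ct + 1) / (n_perm + 1),
            "phi_sc": (hits_sc + 1) / (n_perm + 1),
            "phi_st": (hits_st + 1) / (n_perm + 1),
        }


# ---------------------------------------------------------------------------
# Pairwise Phi_ST and the modified FDR critical value
# ---------------------------------------------------------------------------

def fdr_critical(alpha: float, m: int) -> float:
    """Modified-FDR fixed critical level alpha / sum_{i=1..m} 1/i."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(alpha / np.sum(1.0 / np.arange(1, m + 1)))


def by_stepup(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Full Benjamini-Yekutieli step-up procedure (boolean reject mask)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    thresh = alpha * np.arange(1, m + 1) / (m * c_m)
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        reject[order[: k + 1]] = True
    return reject


@dataclass
class PairwisePhiMatrix:
    populations: list[str]
    phi: pd.DataFrame
    p: pd.DataFrame
    p_crit: float
    m: int
    n_permutations: int
    seed: int | None = None
    excluded: list[str] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        return self.p <= self.p_crit

    def render(self, clamp_negative: bool = True) -> pd.DataFrame:
        """Phi below the diagonal, significance stars above (table layout)."""
        pops = self.populations
        out = pd.DataFrame("", index=pops, columns=pops)
        for i, a in enumerate(pops):
            for j, b in enumerate(pops):
                if i > j:
                    v = self.phi.loc[a, b]
                    if clamp_negative:
                        v = max(v, 0.0)
                    out.loc[a, b] = f"{v:.3f}"
                elif i < j:
                    p = self.p.loc[a, b]
                    stars = (
                        "***" if p < 0.001 else "**" if p < 0.01
                        else "*" if p < 0.05 else "ns"
                    )
                    out.loc[a, b] = stars
                else:
                    out.loc[a, b] = "-"
        return out


def pairwise_phist(
    dist: DistanceMatrix,
    assignment: PopulationAssignment,
    n_perm: int = 100_000,
    seed: int | None = None,
    min_pop_n: int = 3,
    alpha: float = 0.05,
) -> PairwisePhiMatrix:
    """Pairwise Phi_ST, each cell a 2-level AMOVA on the two populations.

    Populations with fewer than ``min_pop_n`` samples are excluded from all
    comparisons (the convention used for tiny samples).  Negative estimates
    are retained; ``render`` clamps them for display only.
    """
    sizes = assignment.sizes()
    pops = [p for p in assignment.populations if sizes.get(p, 0) >= min_pop_n]
    excluded = [p for p in assignment.populations if p not in pops]
    if len(pops) < 2:
        raise ValueError("need at least two populations after exclusion")
    m = len(pops) * (len(pops) - 1) // 2
    phi = pd.DataFrame(0.0, index=pops, columns=pops)
    pval = pd.DataFrame(1.0, index=pops, columns=pops)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = ss.generate_state(m)
    k = 0
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            samples = assignment.samples_of(a) + assignment.samples_of(b)
            sub = dist.submatrix(samples)
            sub_assign = PopulationAssignment(
                {s: assignment.sample_to_population[s] for s in samples}
            )
            res = amova(sub, sub_assign, n_perm=n_perm,
                        seed=int(child_seeds[k] % (2**31)))
            k += 1
            phi.loc[a, b] = phi.loc[b, a] = res.phi_st
            pval.loc[a, b] = pval.loc[b, a] = res.p_values.get("phi_st", np.nan)
    return PairwisePhiMatrix(
        pops, phi, pval, fdr_critical(alpha, m), m, n_perm, seed, excluded
    )


# ---------------------------------------------------------------------------
# Geography, Mantel, PCoA, chi-square
# ---------------------------------------------------------------------------

def great_circle_distance(coord_a, coord_b) -> float:
    """Haversine distance in km between (lat, lon) pairs in decimal degrees."""
    (lat1, lon1), (lat2, lon2) = coord_a, coord_b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"bad coordinate ({lat}, {lon})")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(coords: pd.DataFrame) -> DistanceMatrix:
    pops = list(coords["population"])
    pts = list(zip(coords["lat"], coords["lon"]))
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = great_circle_distance(pts[i], pts[j])
    return DistanceMatrix(pops, m)


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    r_squared: float
    n_pairs: int
    seed: int | None = None


def mantel_ibd(
    genetic: DistanceMatrix,
    geo: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    linearize: bool = True,
) -> MantelResult:
    """Mantel correlation between genetic and geographic distance.

    With ``linearize`` the genetic matrix is transformed to Phi/(1-Phi);
    cells with Phi >= 1 are excluded (warned).  p is the upper-tail fraction
    of row/column permutations with r >= observed, (b+1)/(B+1).
    """
    if genetic.ids != geo.ids:
        geo = geo.submatrix(genetic.ids)
    g = genetic.values.copy()
    n = genetic.n
    mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    if linearize:
        if (g[mask] >= 1.0).any():
            warnings.warn("Phi >= 1 cells excluded from Mantel test", stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = g / (1.0 - g)
        g[np.asarray(genetic.values) >= 1.0] = np.inf  # excluded via finiteness
    y_all = geo.values

    def corr(mat):
        x = mat[mask]
        y = y_all[mask]
        ok = np.isfinite(x)
        x, y = x[ok], y[ok]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return None
        return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))

    r_obs = corr(g)
    if r_obs is None:
        raise ValueError("degenerate (constant) matrix in Mantel test")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = corr(g[np.ix_(perm, perm)])
        if r_perm is None or r_perm >= r_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    n_pairs = int(np.isfinite(g[mask]).sum())
    return MantelResult(r_obs, p, n_perm, r_obs**2, n_pairs, seed)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # items x axes
    percent_variance: np.ndarray
    eigenvalues: np.ndarray


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical scaling: double-center the squared distances, eigendecompose.

    Negative eigenvalues (non-Euclidean input) are dropped from both the
    axes and the percent-variance denominator.
    """
    D2 = dist.values**2
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    evals_pos, evecs_pos = evals[pos], evecs[:, pos]
    coords = evecs_pos * np.sqrt(evals_pos)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        shown = evals_pos[:n_axes]
    else:
        shown = evals_pos
    percent = 100.0 * shown / evals_pos.sum() if evals_pos.size else shown
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        pd.DataFrame(coords, index=dist.ids, columns=cols), percent, evals
    )


def contingency_chisq(counts_table) -> tuple[float, int, float]:
    """Pearson chi-square with df = (r-1)(c-1); zero margins dropped."""
    tab = np.asarray(counts_table, dtype=float)
    if (tab < 0).any():
        raise ValueError("negative counts")
    rows = tab.sum(axis=1) > 0
    cols = tab.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        tab = tab[rows][:, cols]
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(dof), float(p)
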