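"""Diversity indices, mismatch distributions, and molecular-clock arithmetic.

Implements the Nei & Li / Nei & Tajima estimators of haplotype (H_d) and
nucleotide (pi) diversity, the histogram of pairwise differences, a bounded
least-squares fit of the Rogers-Harpending sudden-expansion mismatch curve,
and the rate bookkeeping that converts the fitted mode tau into years via
tau = 2 * mu_genome * t.

Rate conventions.  The "divergence rate" is a two-lineage rate calibrated by
(mean outgroup distance) / (calibration age); the per-lineage rate is half
of it.  Expansion dating uses the per-lineage genome-wide rate u (mutations
per genome per year), so t = tau / (2 u).  This is the only pairing of
conventions that keeps both the calibrated substitution rate and the
expansion date mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import poisson

from .alignment import HaplotypeTable, SequenceAlignment
from .distance import difference_matrix
from .popmap import PopulationAssignment


@dataclass
class DiversityResult:
    H_d: float
    pi: float
    n: int
    h: int


def haplotype_diversity(
    table: HaplotypeTable, population: str | None = None
) -> float:
    """H_d = n/(n-1) * (1 - sum p_i^2) over haplotype frequencies p_i."""
    if population is None:
        counts = table.counts.sum(axis=1).to_numpy(dtype=float)
    else:
        if population not in table.counts.columns:
            raise ValueError(f"unknown population {population!r}")
        counts = table.counts[population].to_numpy(dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    freqs = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(freqs**2)))


def _subset(aln, assignment, population):
    if population is None:
        return aln
    if assignment is None:
        raise ValueError("population given but no assignment")
    return aln.subset(assignment.samples_of(population))


def nucleotide_diversity(
    aln: SequenceAlignment,
    assignment: PopulationAssignment | None = None,
    population: str | None = None,
    complete_deletion: bool = False,
) -> float:
    """Mean per-site pairwise difference over all sample pairs.

    Pairwise deletion (the default) divides each pair's difference count by
    that pair's number of mutually valid sites; ``complete_deletion`` first
    drops every column containing a gap or ambiguity anywhere.
    """
    sub = _subset(aln, assignment, population)
    if sub.n < 2:
        raise ValueError("nucleotide diversity undefined for n < 2")
    if sub.length == 0:
        raise ValueError("empty alignment")
    if complete_deletion:
        arr = sub.to_array()
        ok = np.all(np.isin(arr, [b"A", b"C", b"G", b"T"]), axis=0)
        seqs = ["".join(np.char.decode(arr[i, ok])) for i in range(sub.n)]
        sub = SequenceAlignment(list(sub.sample_ids), seqs)
    d = difference_matrix(sub, per_site=True)
    iu = np.triu_indices(sub.n, k=1)
    return float(np.mean(d.values[iu]))


def diversity_summary(
    aln: SequenceAlignment,
    table: HaplotypeTable,
    assignment: PopulationAssignment,
) -> "list[dict]":
    """Per-population n, h, H_d and pi rows (diversity-table layout)."""
    rows = []
    for pop in assignment.populations:
        n = len(assignment.samples_of(pop))
        h = int((table.counts[pop] > 0).sum()) if pop in table.counts else 0
        row = {"population": pop, "n": n, "h": h, "H_d": np.nan, "pi": np.nan}
        if n >= 2:
            row["H_d"] = haplotype_diversity(table, pop)
            row["pi"] = nucleotide_diversity(aln, assignment, pop)
        rows.append(row)
    return rows


@dataclass
class MismatchResult:
    histogram: np.ndarray  # counts of pairs per difference class 0..max
    mean_diff: float
    tau_hat: float | None = None
    theta0: float | None = None
    theta1: float | None = None
    fit_SSD: float | None = None

    @property
    def n_pairs(self) -> int:
        return int(self.histogram.sum())


def mismatch_distribution(
    aln: SequenceAlignment,
    subset: list[str] | None = None,
) -> MismatchResult:
    """Histogram of pairwise difference counts over all unordered pairs."""
    sub = aln if subset is None else aln.subset(subset)
    if sub.n < 2:
        raise ValueError("need at least two sequences")
    d = difference_matrix(sub)
    iu = np.triu_indices(sub.n, k=1)
    diffs = d.values[iu].astype(int)
    hist = np.bincount(diffs)
    return MismatchResult(hist, float(diffs.mean()))


def _stationary_mismatch(i: np.ndarray, theta: float) -> np.ndarray:
    """Equilibrium mismatch curve F_i(theta) = theta^i / (1+theta)^(i+1)."""
    i = np.asarray(i, dtype=float)
    if theta == 0:
        out = np.zeros_like(i)
        out[i == 0] = 1.0
        return out
    return np.exp(i * np.log(theta) - (i + 1) * np.log1p(theta))


def expected_mismatch(
    i: np.ndarray, tau: float, theta0: float, theta1: float
) -> np.ndarray:
    """Rogers-Harpending expected mismatch after a sudden expansion.

    F_i(tau, theta0, theta1) = F_i(theta1)
        + exp(-tau/theta1) * sum_{j<=i} Pois(j; tau) [F_{i-j}(theta0) - F_{i-j}(theta1)]
    """
    i = np.asarray(i)
    f1 = _stationary_mismatch(i, theta1)
    if tau == 0:
        return f1
    js = np.arange(int(i.max()) + 1)
    pois = poisson.pmf(js, tau)
    diff = _stationary_mismatch(js, theta0) - _stationary_mismatch(js, theta1)
    conv = np.array([np.sum(pois[: k + 1] * diff[: k + 1][::-1]) for k in i])
    decay = np.exp(-tau / theta1) if theta1 > 0 else 0.0
    return np.clip(f1 + decay * conv, 0.0, None)


def fit_sudden_expansion(mismatch: MismatchResult) -> MismatchResult:
    """Bounded nonlinear least squares over (tau, theta0, theta1).

    theta1 is parameterized as theta0 + delta with delta >= 0 so the fitted
    post-expansion size never falls below the pre-expansion size.  Returns a
    new MismatchResult carrying tau_hat, theta0, theta1 and the SSD.
    """
    hist = np.asarray(mismatch.histogram, dtype=float)
    n_pairs = hist.sum()
    if n_pairs == 0:
        raise ValueError("empty mismatch histogram")
    obs = hist / n_pairs
    i = np.arange(len(hist))
    if len(hist) == 1:  # all pairs identical: degenerate, no expansion signal
        return MismatchResult(mismatch.histogram, mismatch.mean_diff, 0.0, 0.0, 0.0, 0.0)
    mean = mismatch.mean_diff

    def residuals(x):
        tau, theta0, delta = x
        return expected_mismatch(i, tau, theta0, theta0 + delta) - obs

    x0 = np.array([max(mean, 0.5), 0.5, max(10.0 * mean, 20.0)])
    fit = least_squares(
        residuals,
        x0,
        bounds=([0.0, 0.0, 0.0], [10.0 * len(hist), 10.0 * mean + 10.0, 1e7]),
        xtol=1e-12,
        ftol=1e-12,
    )
    tau, theta0, delta = fit.x
    ssd = float(np.sum(fit.fun**2))
    return MismatchResult(
        mismatch.histogram, mismatch.mean_diff, float(tau), float(theta0),
        float(theta0 + delta), ssd,
    )


@dataclass
class ClockParams:
    """Calibrated substitution-rate bookkeeping (see module docstring)."""

    divergence_rate: float  # substitutions/site/year, two-lineage
    lineage_rate: float  # divergence_rate / 2
    genome_length: int
    calibration_age: float  # years
    mean_root_distance: float  # substitutions/site

    @property
    def u_genome(self) -> float:
        """Per-lineage mutations per genome per year."""
        return self.lineage_rate * self.genome_length

    @property
    def substitution_interval_years(self) -> float:
        """Mean waiting time between substitutions anywhere in the genome."""
        return 1.0 / (self.divergence_rate * self.genome_length)


def divergence_rate(
    mean_distance: float, calibration_age: float, genome_length: int = 16576
) -> ClockParams:
    """Two-lineage rate from a mean outgroup distance and a calibration age."""
    if mean_distance < 0 or calibration_age <= 0:
        raise ValueError("mean distance must be >= 0 and calibration age > 0")
    rate = mean_distance / calibration_age
    return ClockParams(rate, rate / 2.0, genome_length, calibration_age, mean_distance)


@dataclass
class ExpansionEstimate:
    t_years: float
    tau: float
    u_genome: float  # per-lineage mutations/genome/year


def expansion_time(tau: float, clock: ClockParams) -> ExpansionEstimate:
    """t = tau / (2 u) with u the per-lineage genome-wide yearly rate."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    u = clock.u_genome
    if u <= 0:
        raise ValueError("zero substitution rate")
    return ExpansionEstimate(tau / (2.0 * u), tau, u)
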