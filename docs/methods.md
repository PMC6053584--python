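# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `mitophylogeo`, in the spirit of the model documentation
shipped with coalescent simulators and statistical packages.

## Data model and conventions

Alignments are equal-length sequences over {A, C, G, T, -, IUPAC
ambiguity}; coordinates are 1-based inclusive throughout, matching how
mitogenome features (e.g. a 40-bp control-region repeat at positions
15,696–15,735) are reported. Columns containing any ambiguity character,
and positions explicitly excluded (e.g. unresolved microarray calls), are
skipped by site classification and haplotype identity. Substitution and
indel variation are tallied separately: a column is *variable* when ≥ 2
distinct bases occur among unambiguous calls, *parsimony-informative* when
≥ 2 bases each occur ≥ 2 times, and a *singleton* otherwise, so that
informative + singleton = variable on gap-free data; gap-versus-base
columns count as indel sites. At multi-allelic sites every observed base
pair contributes to the transition/transversion tallies, which reproduces
the usual separate accounting of 3–4-fold degenerate sites.

Reference orientation is the plus strand of the reference mitogenome; no
reverse-complement auto-detection is attempted.

## Microarray base calling

For each position and strand the call is the highest of the four channel
intensities and its confidence is dS/N = (highest − second highest)/sum.
The decision tree is: both strands agree and both dS/N ≥ 0.13 → *strong*;
both ≥ 0.10 with agreement and the call equal to the reference →
*weak_ref*; anything else (strand conflict, dS/N < 0.10, dead or tied
channels) → *ambiguous*, and ambiguous positions join the excluded set.
The thresholds are empirical constants of the assay, exposed as module
constants.

## Diversity and expansion dating

H_d uses the unbiased n/(n−1)(1 − Σp²) estimator. π is the mean per-site
pairwise difference with **pairwise deletion**: each pair's count is
divided by the number of columns valid (plain bases) in both members —
the convention of the cited estimators for data whose gaps are sparse and
scattered; complete deletion is available by flag.

The mismatch histogram counts raw pairwise differences over all unordered
pairs. The sudden-expansion model is the Rogers–Harpending expectation

F_i(τ, θ0, θ1) = F_i(θ1) + e^(−τ/θ1) Σ_{j≤i} Pois(j; τ)[F_{i−j}(θ0) − F_{i−j}(θ1)],

with F_i(θ) = θ^i/(1+θ)^{i+1}, fitted by bounded nonlinear least squares
(scipy `least_squares`, xtol = ftol = 1e-12) to the relative frequencies.
θ1 is parameterized as θ0 + δ with δ ≥ 0 so fitted sizes never shrink
through the "expansion"; τ starts at the observed mean difference. The SSD
is reported so alternative fits are comparable. A histogram with all mass
at zero differences returns τ̂ = 0.

Clock bookkeeping: the *divergence rate* is the two-lineage rate
(mean root distance)/(calibration age); the per-lineage rate is half of
it; expansion dating uses t = τ/(2u) with u the per-lineage genome-wide
yearly rate. This is the only pairing that keeps the calibrated rate
(1.03e-8/site/year from 0.039 over 3.8 My) and the τ = 23.39 → 137 kya
conversion simultaneously consistent. The mean interval between
substitutions is reported from unrounded inputs (≈ 5,878 years for these
values); rounding the rate first gives slightly different figures.
Years and generations are treated as equal for dating.

## AMOVA and related inference

AMOVA follows Excoffier–Smouse–Quattro with the squared inter-haplotype
distance taken as the absolute number of nucleotide differences (pairwise
deletion; a complete-deletion matrix can be supplied instead). Two-level
designs yield Φ_ST; three-level designs yield Φ_CT, Φ_SC, Φ_ST from the
standard n, n′, n″ coefficients. Permutation nulls follow the standard
design — individuals among populations (Φ_ST), individuals among
populations within groups (Φ_SC), whole populations among groups (Φ_CT) —
with p = (b+1)/(B+1) so p is never zero; defaults are 100,000 permutations
for AMOVA/pairwise Φ_ST and 10,000 for Mantel. Negative variance
components and Φ estimates are retained as computed; the table renderer
clamps negatives to .000 for display only, and populations with n < 3 are
excluded from pairwise comparisons by default.

The modified FDR is implemented as the fixed critical value
p_crit = α/Σ_{i=1..m}(1/i), the fixed-critical-level reading of the
Benjamini–Yekutieli correction (m = 78 → .0101, m = 36 → .012); the full
step-up procedure is available as an option.

Mantel tests correlate off-diagonal Φ/(1−Φ) with great-circle distances
(haversine, R = 6,371 km); Φ ≥ 1 cells are excluded (they linearize to
infinity) and the p-value is the upper tail over joint row/column
permutations. PCoA double-centers the squared distances and
eigendecomposes; negative eigenvalues (non-Euclidean input) are dropped
from both the axes and the percent-variance denominator. The χ² test is
Pearson's with (r−1)(c−1) degrees of freedom after dropping zero margins.

## SAMOVA

The search space is K-partitions of populations contiguous on a Delaunay
neighbor graph built from a local equirectangular projection of the
coordinates (complete graph below 4 populations; a path graph for
collinear sites; duplicates jittered deterministically). Each annealing
run starts from a random region-growing partition and proposes moving one
border population to an adjacent group, rejecting moves that would empty
or disconnect a group; improvements in Φ_CT are always accepted,
deteriorations with probability exp(ΔΦ/T) under geometric cooling
(T0 = 0.1, ×0.9 every 100 steps). "100 iterations" is interpreted as 100
independent runs (default; 10,000 steps each), and the best run is
reported with a p-value from permuting populations among groups. The
reported Φ_CT is always reproducible by an independent three-level AMOVA
on the reported grouping, and on small instances the annealer provably
matches exhaustive enumeration over contiguous bipartitions (tested).
Because the three-level sums of squares depend on the grouping only
through population-pair aggregates, each proposal is evaluated in O(P²).

## Phylogeny

Neighbor joining is Saitou–Nei with two determinism guarantees: among
tied Q-minima the pair whose sorted cluster labels are lexicographically
smallest is joined, and negative branch estimates are clamped to zero
with the deficit re-added to the sister branch (preserving the pair's
path length). Bootstrap resamples columns with replacement; distance
matrices for replicates are assembled from precomputed column-pattern
mismatch matrices, and support is the percentage of replicate trees
containing each internal bipartition of the full-data tree. Rooting
places the root at the midpoint of the outgroup's pendant edge.

Clock dating computes the rate as (mean root-to-tip path)/(calibration
age) and each node's age as its mean path to descendant tips divided by
that rate. Mean-path depths need not be monotone on non-ultrametric
trees, so ages are clamped to never exceed the parent's — documented here
because it makes dated ages reproducible and ordered. Bayesian tree
inference and posterior node supports are out of scope by design; the
clock operates on the NJ tree, and the Monte Carlo module accepts any
newick tree so externally inferred topologies can be tested.

## Haplotype network

Haplotypes are joined in order of increasing pairwise distance (ties by
total frequency, then lexicographic id); joins longer than one step are
filled with latent single-step nodes; joins beyond the connection limit
are refused, which can leave several components. When a pair is already
connected, a strictly shorter route is added; an equal-length alternative
is recorded and, with loop retention enabled (default), drawn only when
it is a direct single-step edge — multi-step equal alternatives would
merely duplicate an existing path through fresh latent nodes. Latent
nodes are abstract step counters, not base-by-base ancestral
reconstructions. Indel steps count as one change.

The connection limit is the largest j whose parsimony probability meets
the confidence level. The parsimony probability here is the no-hidden-
multiple-hit probability under uniform finite-sites mutation: P(j) =
Π_{i<j}(1 − i/m), computed by the recursion P(j) = P(j−1)(1 − (j−1)/m).
It is 1 for j ≤ 1, strictly decreasing afterwards, and non-decreasing in
sequence length at fixed confidence; for a 16,576-bp genome at 90%
confidence the limit is 59 steps. This is this package's own estimator of
the classical "probability of parsimony"; software lineages differ in the
exact recursion they use, so limits computed here should be quoted with
the formula above.

## Monte Carlo test of phylogeographic structure

A partition model assigns states 1–4 to populations; samples of
unassigned populations are pruned from the tree before anything is
computed. The observed statistic is the unit-cost parsimony length L of
the tip character, computed by Hartigan's count-based downpass (exact on
multifurcations; verified against a Sankoff dynamic program). "Random
trees" are realized as uniform random permutations of the tip states on
the fixed observed topology — this preserves the partition counts N and
makes C% well-defined; C% is the inclusive tail 100·#(L_rand ≤ L_obs)/
n_rand, with significance stars at .05/.01/.001 and an additional
(b+1)/(B+1) p-value. The default is 10,000 randomizations. Null lengths
are computed for all permutations at once by vectorizing the downpass
over columns.

## Synthetic-data generator

The generator is a structured coalescent (msprime, ploidy 1, one
non-recombining locus) with finite-sites mutation layered on the
genealogy by this package: substitutions are Poisson on branches, each
hitting a uniform site, transitions with probability κ/(κ+1); single-base
indels are independent rare events writing an absorbing gap character.
Multiple hits and 3–4-fold degenerate sites can therefore occur, as in
real mitogenome data. mtDNA is assumed clonal (no recombination, no
selection), and repeat-array length polymorphism is not simulated.

Defaults are chosen once to emulate the study regime: 14 populations with
sample sizes (7, 10, 18, 12, 14, 14, 10, 2, 11, 13, 11, 11, 10, 10) —
153 samples including one n = 2 location that downstream analyses exclude
— 16,576 bp, per-site mutation rate 2.3e-8/generation with deme size
3,600 so that within-population θ per site ≈ 0.0023 (the observed π
scale), island-model migration 9.2e-5 per deme pair so the expected
pairwise Φ_ST is ≈ 0.098, ts:tv κ = 7.6 (≈ 779 transitions / 102
transversions), and an indel rate three orders below the substitution
rate. Sudden expansions are specified directly in mismatch units
(τ, θ0, θ1) and converted through τ = 2ut; two-group split scenarios take
a split time and group labels, with migration only within groups.
Generations and years are conflated 1:1 in simulation truth; calendar
conversion happens only in the clock/expansion modules.

Ground truth in the sidecar is computed analytically, not from the
realized data: expected pairwise Φ_ST comes from the two-lineage
structured-coalescent Markov chain ((T_between − T_within)/T_between with
exact mean coalescence times; for split models the pre-split phase is
integrated with a matrix exponential), verified against msprime's
demography debugger. Truth Φ_ST is not defined for time-varying sizes and
is omitted for expansion scenarios. Synthetic coordinates place
populations along a North-Atlantic-like arc with groups contiguous, so
SAMOVA's spatial constraint is honest.

What the generator does **not** emulate: star-like post-glacial
genealogies inside an equilibrium island model (real data mix both, so
singleton/informative ratios differ from equilibrium expectations),
selection, sequencing error, and repeat-copy-number variation. Passing
the recovery tests shows the estimators are correct under the stated
model, not that real data meet the model's assumptions.

## Pipeline, seeds, and problem sizes

One logical seed fans out to per-stage seeds via numpy `SeedSequence`
spawn keys; the stage→counter map is recorded in the run log so stages
can be rerun in isolation, and identical seeds give byte-identical
reports. Reports are TSV/JSON only.

Library defaults match the emulated study design's analysis scales (100,000 AMOVA
permutations, 10,000 Mantel permutations, 10,000 bootstrap replicates,
10,000 randomizations, 100 SAMOVA runs). The test suite and examples run
the same code at reduced scales chosen as this package's validation
design: null calibrations at 200 runs × 500 permutations, recovery at 20
replicates, the end-to-end run at 2,000 AMOVA permutations and 100
bootstrap replicates. The Monte Carlo null calibration uses ~150-tip
trees because the parsimony length is integer-valued: on tiny trees its
support is too coarse for a meaningful comparison of C% against a
continuous uniform.

## Known limitations

* The island-model equilibrium underestimates the singleton excess of
  recently expanded real populations; site-frequency-spectrum shapes are
  not part of any acceptance check.
* Mean-path clock ages are a point summary without uncertainty; no HPD
  intervals are produced.
* The connection-limit estimator is a principled stand-alone model (see
  above), not a byte-level reimplementation of any particular network
  program.
* SAMOVA p-values inherit the granularity of permuting few populations
  among groups; the permutation count is recorded so this is explicit.
* χ² p-values use the asymptotic distribution; sparse haplogroup-by-
  population tables should be interpreted with care.
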