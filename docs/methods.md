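# Methods

## The zero problem

A cell of an OTU × sample count table can be zero because the taxon is
absent from that community (structural zero) or because it was present but
not sampled at the realized sequencing depth (sampling zero). The two are
indistinguishable in the table, and downstream correlation estimates depend
strongly on the convention chosen. `zerolink` treats zero as the
missing-value sentinel throughout; no separate NA code exists.

## Preprocessing

Profiles are read from tab-separated text (taxon rows, sample columns,
`#` comments skipped). Typical cleaning follows the order: drop aggregate
rows (e.g. an "unclassified" catch-all), rarefy, frequency-filter.

* **Rarefaction** subsamples each sample column to a common depth without
  replacement (one multivariate hypergeometric draw per sample), so
  per-sample totals are exact and no taxon exceeds its observed count.
  Samples shallower than the target depth are dropped with a warning.
* **Frequency filtering** keeps taxa whose presence count (samples with
  value > 0, evaluated after rarefaction) falls in a band, e.g. ≥ 60
  samples for "abundant/occasional" taxa or 30–60 for less frequent ones.
  The operation is idempotent.
* **CLR** is computed per sample with natural logs,
  y = log x − mean(log x), and demands strictly positive input: zeros must
  have been handled first, either by an upstream policy or by an explicit
  pseudocount argument. Columns sum to zero within 1e−9 and the transform
  is invariant to per-sample rescaling.

When correlating CLR-transformed values under the pair-level policies, the
zero mask must describe the *pre-transform* counts (CLR values can be
legitimately zero or negative). `pair_filter` and `correlate_all` therefore
accept an explicit zero mask; the CLI captures it from the raw profile
automatically.

## The six policies

Policies 1–3 transform the profile once: identity; kNN imputation; constant
fill with a pseudo-value (default 0.01, the convention of pipelines that
pre-fill unpaired zeros). Policies 4–6 act per taxon pair: drop samples
where both values are zero and fill the remaining unpaired zeros (4); drop
paired zeros and keep unpaired zeros (5); keep complete cases only (6).
Policy 5 — paired abundance values only — is the benchmark standard, the
treatment the comparison is anchored to.

For every pair the valid-sample counts obey
n₆ ≤ n₄ = n₅ ≤ n, policies 4 and 5 coincide when a pair has no unpaired
zeros, and all six coincide on zero-free pairs; these algebraic facts are
enforced by property tests.

### kNN imputation

Taxa are cases and samples variables. For a zero cell (i, s): donors are
taxa observed at s that share ≥ 1 mutually observed sample with i; the
distance is the root-mean-square difference of per-sample standardized
values (each sample column centred/scaled on its observed entries) over
mutually observed samples; the imputed value is the Gaussian-kernel
weighted mean, w = exp(−d²/2·bandwidth²), of the k = 10 nearest donors'
raw values at s (uniform weights if every kernel underflows). k, the
bandwidth and the weighting are exposed. Cells with no donors, and taxa
with fewer than k donors or no observed values at all, are left at zero
and reported in a non-imputable table rather than silently filled — rare
taxa routinely end up there, which is itself a diagnostic.

## Sequential pairwise correlation

Coefficients are computed pair by pair, never from one whole-matrix call,
so each pair carries its own filtered sample set and valid count.
A pair enters the output only if it exceeds the minimum overlap (strictly
more than 30 paired valid observations; applied to the pair-level policies
by default, extensible to all). Undefined coefficients — constant vectors
after filtering, frequent under policy 6 — are dropped and logged, never
recorded as 0: a fabricated zero would silently interact with the |r|
cutoff later.

Pearson, Spearman (mid-ranks) and Kendall τ_b are delegated to
`scipy.stats`. P-values are the parametric approximations: Student-t with
n − 2 degrees of freedom for Pearson and Spearman, and the normal
approximation for Kendall. For Kendall with ties the tie-corrected
asymptotic variance is used; in the tie-free case it reduces exactly to
z = 3(C − D)/√(n(n−1)(2n+5)/2). An exact-style permutation p-value is
available for small n. No multiple-testing correction is applied by
default — networks are thresholded on raw p < 0.001 — though the helper is
trivially composable with any correction the user prefers.

Pair iteration is canonical (sorted taxon IDs), making outputs independent
of row order; `subsample_pairs` draws a fixed-size random subset (e.g.
10,000 pairs for plotting) deterministically from a seed.

## SparCC

Sequencing data are compositional: only relative abundances are observed.
SparCC estimates correlations of the latent *basis* abundances from the
log-ratio variation matrix t_ij = Var_s log(f_i/f_j), using
t_ij = ω_i + ω_j − 2ρ_ij√(ω_iω_j). Under the sparsity assumption the row
sums of t yield a linear system for the basis variances ω (solved by least
squares); the most strongly correlated pair above |ρ| = 0.1 is then removed
from the row sums and the system re-solved, for up to 10 rounds. Sampling
noise is integrated out by 20 Dirichlet resamples of the per-sample
fractions (pseudo-count prior 1 on every element, per the original
algorithm), aggregated by the median (mean available). All randomness
flows from one seed.

Numerical notes: ρ is clipped to [−1, 1] after solving; non-positive basis
variances (the sparsity approximation failing, common at small D) are
replaced by the median positive basis variance with a logged warning, which
keeps the affected correlations bounded instead of saturating at ±1; D < 4
is rejected as ill-posed. Significance uses two-sided permutation p-values
(every taxon's counts shuffled independently across samples, reduced
resample count, add-one estimator), since the basis-correlation null has no
convenient parametric form.

On zero-light data SparCC and Pearson on the CLR-transformed profile
estimate the same log-scale associations; their off-diagonal coefficients
agree with R² ≈ 0.98 on the generator's zero-light profile. Pearson on raw
counts is *not* the right comparison on synthetic log-normal data — the
skewed scale drags R² to ≈ 0.5 without invalidating either estimator.

## Networks

Edges are kept under strict cutoffs (|r| > 0.6 and p < 0.001 by default):
positive edges form the co-occurrence network, negative edges the
co-exclusive network; nodes are endpoints of kept edges. Topology metrics
follow the Cytoscape NetworkAnalyzer conventions: density 2E/N(N−1),
average neighbours 2E/N, heterogeneity √Var(k)/mean(k), centralization
(N/(N−2))(k_max/(N−1) − density), clustering averaged over all nodes with
degree < 2 contributing 0. The characteristic path length averages over
all connected node pairs; diameter and radius are reported for the largest
component with per-component values logged — these association networks
are typically fragmented. Metrics undefined for very small graphs are
returned as NaN markers, never raised.

Hub subnetworks take the top-k (default 10) highest-degree nodes plus all
their first neighbours, with degree ties at the boundary broken
lexicographically and recorded. Consensus networks intersect edge sets
(unordered pair + sign) across members; consensus nodes are the endpoints
of surviving edges, while `overlap_counts` reports the bare node-set
intersection separately, so both readings of "overlapped nodes" are
available. Export formats are GraphML (Cytoscape-loadable) and an edge TSV
that round-trips.

## Synthetic profiles

The generator draws, per sample, a latent Gaussian vector with a target
correlation matrix (identity plus planted pairs, checked for positive
definiteness), maps it to log-normal basis abundances on a shifted
power-law rank backbone (r + shift)^−decay, applies a Bernoulli occupancy
mask, closes to fractions, and draws multinomial counts at the sequencing
depth. Sampling zeros arise naturally from the depth; structural zeros
from occupancy. The returned ground truth is the latent correlation
matrix. For a Gaussian copula the population Spearman of a planted pair is
(6/π)·asin(ρ/2), slightly below ρ itself; recovery tests compare against
that value.

Two design points matter and are deliberate:

* **Rank shift.** A pure power law with exponent ≈ 2.6 would hand the top
  taxon most of the reads, and the shared-denominator (closure) noise of
  that one taxon would swamp planted signals everywhere else. The shift
  (default 10 in the survey-like spec) caps dominance while preserving the
  long tail. Planted pairs sit at moderately abundant ranks (15–32) for the
  same reason.
* **Per-sample richness effect.** Real surveys differ site-to-site in how
  many taxa they host, so structural zeros co-occur across taxa within a
  sample. The generator adds a N(0, richness_sd²) sample effect on the
  occupancy logit (taxa with occupancy 1 stay at 1). Without it, zero
  patterns are independent across taxa and the policy comparison loses the
  very effect it exists to expose: shared zero samples are what let
  kept-as-is or pseudo-filled zeros inflate rank correlations relative to
  the paired-exclusion standard.

`tara_like_spec()` freezes a survey-like regime: 1,500 taxa × 139 samples
at 39,410 reads per sample, rank decay 2.6 with shift 10, σ_log 1.2,
occupancy (r/40)^−0.5 capped at 1, richness_sd 2.0, six planted pairs
(ρ = ±0.6…0.8). With these defaults the zero fraction is ≈ 0.87 and ≈ 140
taxa pass a ≥ 60-sample frequency filter — the scale at which the full
six-policy benchmark runs in well under a minute.

What the generator does *not* emulate: phylogenetic or taxonomic structure,
environmental covariates driving many taxa jointly (beyond the richness
effect), time-series dynamics, and chimeric/technical artefacts. Passing
tests therefore demonstrate correctness of the estimators and the policy
algebra under a controlled truth, not that any particular policy is optimal
on real ocean data.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen so
the whole suite runs in well under a minute of compute per heavy check:
10 × 50 profiles for oracle-exactness, 200 random pairs for policy algebra,
all permutations at n ≤ 6 for rank-statistic enumeration, D = 50 × 200
samples for SparCC recovery, and the 1,500 × 139 survey-like profile for
the end-to-end benchmark. Every stochastic path (rarefaction, resampling,
permutation tests, the generator) takes an explicit integer seed, and equal
seeds give bit-identical results.

## Known limitations

* The kNN imputation distance uses mutually observed entries only; for very
  sparse taxa it degenerates and the taxon lands in the non-imputable
  report rather than receiving a value.
* SparCC's sparsity assumption fails when many pairs are strongly
  correlated; the iterative exclusion mitigates but does not remove this,
  and negative-variance fallbacks are logged when it breaks.
* Parametric p-values are approximations; at small valid counts (n barely
  above the overlap minimum) the permutation option is preferable.
* Consensus networks require identical taxon naming across member runs; no
  identifier reconciliation is attempted.
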