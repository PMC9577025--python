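"""SparCC: sparse compositional correlation from log-ratio variances.

Sequencing data are compositional — each sample carries only relative
information — so correlations computed directly on fractions can be
spurious. SparCC estimates the correlations of the unobserved *basis*
abundances from the matrix of log-ratio variances

    t_ij = Var_s[ log(f_i(s) / f_j(s)) ] = w_i + w_j - 2 rho_ij sqrt(w_i w_j)

where w_i is the basis log-variance of component i and rho_ij the basis
correlation. Under the sparsity assumption (most rho_ij ~ 0) the row sums of
t give a linear system for the w_i; pairs that come out strongly correlated
are then excluded from the row sums and the system re-solved, for a few
rounds. Sampling noise is integrated out by averaging over Dirichlet
posterior draws of the per-sample fractions (pseudo-count prior of 1 on each
element).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .profile import AbundanceProfile, ProfileError

log = logging.getLogger(__name__)

__all__ = ["SparccResult", "sparcc_estimate", "sparcc_pvalues", "sparcc_to_pairs"]


@dataclass
class SparccResult:
    """Estimated basis correlation matrix for a profile.

    ``rho`` is symmetric with unit diagonal, off-diagonals clipped to
    [-1, 1]. ``excluded_pairs`` lists taxon-ID pairs removed from the
    sparsity system during iterative exclusion (union over resamples).
    """

    taxon_ids: list[str]
    rho: np.ndarray
    n_iterations_used: int
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        D = len(self.taxon_ids)
        if self.rho.shape != (D, D):
            raise ProfileError("rho shape does not match taxon count")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ProfileError("rho must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0):
            raise ProfileError("rho diagonal must be 1")


def _variation_matrix(log_frac: np.ndarray) -> np.ndarray:
    """t_ij = sample variance of log(f_i) - log(f_j); shape (D, D)."""
    cov = np.cov(log_frac)                       # D x D, ddof=1
    d = np.diag(cov)
    return d[:, None] + d[None, :] - 2.0 * cov


def _basis_correlations(
    t: np.ndarray,
    exclusion_threshold: float,
    max_exclusion_rounds: int,
) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Solve the sparsity system for one variation matrix, with exclusion."""
    D = t.shape[0]
    excluded: set[tuple[int, int]] = set()
    include = np.ones((D, D), dtype=bool)
    np.fill_diagonal(include, False)
    rho = np.zeros((D, D))
    for _ in range(max_exclusion_rounds + 1):
        # row sums over included partners: t_i = (|S_i| - 1) w_i + sum_{j in S_i} w_j
        A = include.astype(float)
        A[np.arange(D), np.arange(D)] = include.sum(axis=1) - 1
        tvec = (t * include).sum(axis=1)
        w, *_ = np.linalg.lstsq(A, tvec, rcond=None)
        bad = w <= 0
        if bad.any():
            # sparsity approximation broke down for these components (common
            # at small D); fall back to the median basis variance so their
            # correlations stay bounded instead of saturating at +-1
            log.warning("sparcc: %d negative basis variances replaced", int(bad.sum()))
            fallback = np.median(w[~bad]) if (~bad).any() else 1.0
            w = np.where(bad, fallback, w)
        sw = np.sqrt(w)
        with np.errstate(invalid="ignore"):
            rho = (w[:, None] + w[None, :] - t) / (2.0 * sw[:, None] * sw[None, :])
        np.fill_diagonal(rho, 1.0)
        rho = np.clip(rho, -1.0, 1.0)
        # exclude the single most correlated still-included pair above threshold
        masked = np.where(include, np.abs(rho), -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if not np.isfinite(masked[i, j]) or masked[i, j] <= exclusion_threshold:
            break
        if len(excluded) >= max_exclusion_rounds:
            break
        excluded.add((min(i, j), max(i, j)))
        include[i, j] = include[j, i] = False
    return rho, excluded


def sparcc_estimate(
    profile: AbundanceProfile,
    n_resamples: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    pseudocount: float = 1.0,
    seed: int = 0,
    aggregate: str = "median",
) -> SparccResult:
    """Estimate basis correlations from a raw (zero-containing) count profile.

    Each of the ``n_resamples`` iterations draws per-sample fractions from a
    Dirichlet posterior with ``pseudocount`` added to every count, computes
    the log-ratio variation matrix, and solves the sparsity system with
    iterative pair exclusion. The final rho aggregates resamples by the
    median (or mean). Deterministic given ``seed``.
    """
    D, S = profile.shape
    if D < 4:
        raise ProfileError("SparCC needs at least 4 taxa (basis system ill-posed)")
    if n_resamples < 1:
        raise ProfileError("n_resamples must be >= 1")
    if aggregate not in ("median", "mean"):
        raise ProfileError("aggregate must be 'median' or 'mean'")
    counts = profile.values
    if counts.size and (counts.min() < 0 or not np.all(counts == np.round(counts))):
        raise ProfileError("SparCC expects non-negative integer counts")
    rng = np.random.default_rng(seed)
    alpha = counts + pseudocount                  # D x S
    rhos = np.empty((n_resamples, D, D))
    excluded_ids: set[tuple[str, str]] = set()
    for it in range(n_resamples):
        # Dirichlet draw per sample: gamma variates normalized column-wise
        g = rng.standard_gamma(alpha)
        frac = g / g.sum(axis=0, keepdims=True)
        t = _variation_matrix(np.log(frac))
        rho, excl = _basis_correlations(t, exclusion_threshold, max_exclusion_rounds)
        rhos[it] = rho
        excluded_ids.update(
            (profile.taxon_ids[i], profile.taxon_ids[j]) for i, j in excl
        )
    agg = np.median(rhos, axis=0) if aggregate == "median" else rhos.mean(axis=0)
    agg = np.clip((agg + agg.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(agg, 1.0)
    return SparccResult(
        list(profile.taxon_ids), agg, n_iterations_used=n_resamples,
        excluded_pairs=sorted(excluded_ids),
    )


def sparcc_pvalues(
    profile: AbundanceProfile,
    observed: SparccResult,
    n_permutations: int,
    seed: int = 0,
    n_resamples: int = 5,
    **estimate_kwargs,
) -> np.ndarray:
    """Two-sided permutation p-values for a SparCC estimate.

    Each permutation independently shuffles every taxon's counts across
    samples (destroying pairwise association while preserving marginals),
    re-estimates rho with a reduced resample count, and the add-one
    estimator ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + B)`` is applied
    cell-wise.
    """
    if n_permutations < 1:
        raise ProfileError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    D = profile.n_taxa
    hits = np.zeros((D, D))
    obs = np.abs(observed.rho)
    for b in range(n_permutations):
        perm = np.empty_like(profile.values)
        for i in range(D):
            perm[i] = rng.permutation(profile.values[i])
        pprof = AbundanceProfile(
            list(profile.taxon_ids), list(profile.sample_ids), perm,
            {**profile.meta, "permuted": True},
        )
        res = sparcc_estimate(
            pprof, n_resamples=n_resamples,
            seed=int(rng.integers(2**31 - 1)), **estimate_kwargs,
        )
        hits += (np.abs(res.rho) >= obs)
    p = (1.0 + hits) / (1.0 + n_permutations)
    np.fill_diagonal(p, 1.0)
    return p


def sparcc_to_pairs(result: SparccResult, pvalues: np.ndarray | None = None):
    """Flatten a SparCC matrix into PairCorrelation records (method='sparcc')."""
    from .correlation import PairCorrelation

    D = len(result.taxon_ids)
    order = sorted(range(D), key=lambda i: result.taxon_ids[i])
    out = []
    for a, b in itertools.combinations(order, 2):
        out.append(PairCorrelation(
            result.taxon_ids[a], result.taxon_ids[b],
            r=float(result.rho[a, b]),
            p=float(pvalues[a, b]) if pvalues is not None else float("nan"),
            n_valid=0, method="sparcc", policy=1,
        ))
    return out
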