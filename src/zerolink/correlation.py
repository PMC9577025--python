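"""Sequential pairwise correlation inference under the zero policies.

Coefficients are computed pair by pair — never from a whole-matrix call — so
that each taxon pair can receive its own zero filtering and its own valid
sample count, as required by the pair-level policies. Pearson, Spearman
(mid-ranks) and Kendall tau-b are delegated to scipy.stats; p-values are the
parametric approximations (Student-t for Pearson/Spearman, normal for
Kendall), with an exact permutation p available for small n.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import FilterPolicy, PAIR_LEVEL, POLICY_NAMES, pair_filter
from .profile import AbundanceProfile, ProfileError

log = logging.getLogger(__name__)

__all__ = [
    "PairCorrelation",
    "pearson",
    "spearman",
    "kendall_tau_b",
    "correlate_all",
    "subsample_pairs",
    "write_edge_tsv",
    "read_edge_tsv",
]

METHODS = ("pearson", "spearman", "kendall")


@dataclass(frozen=True)
class PairCorrelation:
    """One taxon-pair correlation record; ``taxon_i < taxon_j`` canonically."""

    taxon_i: str
    taxon_j: str
    r: float
    p: float
    n_valid: int
    method: str
    policy: int

    def __post_init__(self) -> None:
        if self.taxon_i == self.taxon_j:
            raise ValueError("self-correlation records are not allowed")
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"coefficient out of range: {self.r}")


def _as_clean_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray] | None:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ProfileError("x and y must be aligned 1-D vectors")
    if len(x) < min_n:
        return None
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-distribution p-value.

    Returns ``(nan, nan)`` when undefined (n < 3 or a constant vector);
    callers drop such pairs rather than treating them as zero correlation.
    """
    pair = _as_clean_pair(x, y, 3)
    if pair is None:
        return (float("nan"), float("nan"))
    x, y = pair
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    res = stats.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Rank correlation: Pearson on mid-ranks, t-approximation p-value."""
    pair = _as_clean_pair(x, y, 3)
    if pair is None:
        return (float("nan"), float("nan"))
    x, y = pair
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    if np.isnan(rho):
        return (float("nan"), float("nan"))
    return (float(rho), float(p))


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) with two-sided normal-approximation p-value."""
    pair = _as_clean_pair(x, y, 3)
    if pair is None:
        return (float("nan"), float("nan"))
    x, y = pair
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    if np.isnan(res.statistic):
        return (float("nan"), float("nan"))
    return (float(res.statistic), float(res.pvalue))


_METHOD_FUNCS = {"pearson": pearson, "spearman": spearman, "kendall": kendall_tau_b}


def permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Exact-style permutation p-value (add-one estimator) for small n."""
    func = _METHOD_FUNCS[method]
    r_obs, _ = func(x, y)
    if np.isnan(r_obs):
        return float("nan")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    hits = 0
    for _ in range(n_permutations):
        r_perm, _ = func(x, rng.permutation(y))
        if not np.isnan(r_perm) and abs(r_perm) >= abs(r_obs) - 1e-15:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def correlate_all(
    profile: AbundanceProfile,
    method: str,
    policy: int | FilterPolicy,
    min_overlap: int = 30,
    pseudo_value: float = 0.01,
    zero_mask: np.ndarray | None = None,
    apply_min_overlap_to_all: bool = False,
) -> list[PairCorrelation]:
    """Correlate every unordered taxon pair sequentially under one policy.

    For profile-level policies (1-3) the profile is expected to be treated
    already (``treat_profile``); pair-level policies (4-6) are applied here
    via :func:`pair_filter`. Pairs whose valid-sample count does not exceed
    ``min_overlap`` (strict; pair-level policies only, unless
    ``apply_min_overlap_to_all``) and pairs with undefined coefficients are
    omitted and tallied in a skip log. ``zero_mask`` supplies the zero
    pattern explicitly for transformed (e.g. CLR) matrices whose cell values
    no longer encode missingness.

    Output order is canonical (sorted taxon IDs) and independent of the
    profile's row order.
    """
    if method not in _METHOD_FUNCS:
        raise ProfileError(f"unknown method {method!r}; expected one of {METHODS}")
    code = policy.code if isinstance(policy, FilterPolicy) else int(policy)
    if code not in POLICY_NAMES:
        raise ProfileError(f"unknown policy code {code}")
    if isinstance(policy, FilterPolicy):
        pseudo_value = policy.pseudo_value
    func = _METHOD_FUNCS[method]
    mask = np.asarray(zero_mask, dtype=bool) if zero_mask is not None else profile.zero_mask()
    if mask.shape != profile.shape:
        raise ProfileError("zero_mask shape mismatch")

    order = sorted(range(profile.n_taxa), key=lambda i: profile.taxon_ids[i])
    enforce_overlap = (code in PAIR_LEVEL) or apply_min_overlap_to_all
    results: list[PairCorrelation] = []
    skipped = {"min_overlap": 0, "undefined": 0}
    for a, b in itertools.combinations(order, 2):
        fp = pair_filter(
            profile.values[a], profile.values[b], code, pseudo_value,
            sample_ids=profile.sample_ids,
            x_zero=mask[a], y_zero=mask[b],
        )
        if enforce_overlap and fp.n_valid <= min_overlap:
            skipped["min_overlap"] += 1
            continue
        r, p = func(fp.x, fp.y)
        if np.isnan(r):
            skipped["undefined"] += 1
            continue
        results.append(PairCorrelation(
            profile.taxon_ids[a], profile.taxon_ids[b],
            r=r, p=p, n_valid=fp.n_valid, method=method, policy=code,
        ))
    log.info(
        "correlate_all(%s, policy %d): %d pairs kept, %d below overlap, %d undefined",
        method, code, len(results), skipped["min_overlap"], skipped["undefined"],
    )
    return results


def subsample_pairs(
    results: Sequence[PairCorrelation], m: int, seed: int
) -> list[PairCorrelation]:
    """Uniformly sample ``m`` pair records without replacement (deterministic)."""
    if m > len(results):
        raise ProfileError(f"cannot sample {m} pairs from {len(results)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(results), size=m, replace=False)
    return [results[i] for i in idx]


# -- edge-list I/O ---------------------------------------------------------

_EDGE_COLUMNS = ["taxon_i", "taxon_j", "r", "p", "n_valid", "method", "policy"]


def write_edge_tsv(results: Sequence[PairCorrelation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(c.taxon_i, c.taxon_j, c.r, c.p, c.n_valid, c.method, c.policy) for c in results],
        columns=_EDGE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_edge_tsv(path: str | Path) -> list[PairCorrelation]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_EDGE_COLUMNS) - set(frame.columns)
    if missing:
        raise ProfileError(f"edge TSV missing columns: {sorted(missing)}")
    return [
        PairCorrelation(str(row.taxon_i), str(row.taxon_j), float(row.r),
                        float(row.p), int(row.n_valid), str(row.method), int(row.policy))
        for row in frame.itertuples(index=False)
    ]
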