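"""The six zero-value treatment policies.

Zero values in abundance profiles are ambiguous: a taxon may be biologically
absent (structural zero) or merely undetected at the realized sequencing
depth (sampling zero). This module treats zero as the missing-value sentinel
and implements six policies for handling it before correlation inference:

1. ZERO_AS_IS        keep zeros as 0 (no treatment)
2. KNN_IMPUTE        replace zeros with k-nearest-neighbour imputed values
3. FILL_PSEUDO       replace every zero with a small pseudo-value (0.01)
4. DROP_PAIRED_FILL  per pair, drop samples where both taxa are zero; fill
                     remaining (unpaired) zeros with the pseudo-value
5. DROP_PAIRED_KEEP  per pair, drop samples where both taxa are zero; keep
                     unpaired zeros as 0
6. COMPLETE_CASE     per pair, drop any sample where either taxon is zero

Policies 1-3 transform the whole profile; 4-6 act pair-by-pair and produce
a :class:`FilteredPair` for each taxon pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .profile import AbundanceProfile, ProfileError

log = logging.getLogger(__name__)

__all__ = [
    "FilterPolicy",
    "FilteredPair",
    "POLICY_NAMES",
    "treat_profile",
    "knn_impute",
    "pair_filter",
    "count_eligible_pairs",
    "write_non_imputable_report",
]

POLICY_NAMES = {
    1: "ZERO_AS_IS",
    2: "KNN_IMPUTE",
    3: "FILL_PSEUDO",
    4: "DROP_PAIRED_FILL",
    5: "DROP_PAIRED_KEEP",
    6: "COMPLETE_CASE",
}

PROFILE_LEVEL = frozenset({1, 2, 3})
PAIR_LEVEL = frozenset({4, 5, 6})


@dataclass(frozen=True)
class FilterPolicy:
    """One of the six zero-treatment strategies.

    ``pseudo_value`` is the fill value used by FILL_PSEUDO (policy 3) and for
    unpaired zeros under DROP_PAIRED_FILL (policy 4); 0.01 follows the MENA
    pipeline default.
    """

    code: int
    pseudo_value: float = 0.01

    def __post_init__(self) -> None:
        if self.code not in POLICY_NAMES:
            raise ValueError(f"unknown policy code {self.code}; expected 1-6")
        if self.pseudo_value <= 0:
            raise ValueError("pseudo_value must be > 0")

    @property
    def name(self) -> str:
        return POLICY_NAMES[self.code]

    @property
    def is_profile_level(self) -> bool:
        return self.code in PROFILE_LEVEL


@dataclass
class FilteredPair:
    """Aligned value vectors for one taxon pair after zero filtering."""

    x: np.ndarray
    y: np.ndarray
    kept_sample_ids: list[str]
    n_valid: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.kept_sample_ids) == self.n_valid):
            raise ValueError("FilteredPair length invariant violated")


# -- profile-level policies (1-3) -----------------------------------------


def treat_profile(
    profile: AbundanceProfile,
    policy: int | FilterPolicy,
    pseudo_value: float = 0.01,
    k: int = 10,
) -> AbundanceProfile:
    """Apply a profile-level policy (1, 2 or 3) to the whole matrix.

    Policy 1 is the identity; policy 3 replaces every zero cell by
    ``pseudo_value``; policy 2 runs :func:`knn_impute`. Non-zero cells are
    never altered. Pair-level policies (4-6) raise, directing the caller to
    :func:`pair_filter`.
    """
    code = policy.code if isinstance(policy, FilterPolicy) else int(policy)
    if isinstance(policy, FilterPolicy):
        pseudo_value = policy.pseudo_value
    if code in PAIR_LEVEL:
        raise ProfileError(
            f"policy {code} ({POLICY_NAMES[code]}) is pair-level; use pair_filter"
        )
    if code == 1:
        return profile.copy(policy=1)
    if code == 3:
        vals = profile.values.copy()
        vals[vals == 0] = pseudo_value
        return AbundanceProfile(
            list(profile.taxon_ids), list(profile.sample_ids), vals,
            {**profile.meta, "policy": 3, "pseudo_value": pseudo_value, "state": "real"},
        )
    return knn_impute(profile, k=k)


def knn_impute(
    profile: AbundanceProfile,
    k: int = 10,
    bandwidth: float = 1.0,
) -> AbundanceProfile:
    """Replace zeros by k-nearest-neighbour expectations across taxa.

    Taxa are the cases and samples the variables. For a zero cell (i, s) the
    donors are taxa observed (non-zero) at sample s that share at least one
    mutually observed sample with taxon i. Distance between two taxa is the
    root-mean-square difference of per-sample standardized values over their
    mutually observed samples; the imputed value is the Gaussian-kernel
    weighted mean ``w = exp(-d^2 / (2 * bandwidth^2))`` of the k nearest
    donors' raw values at s (uniform weights if all kernels underflow).

    Cells that cannot be imputed (all-zero taxon row, no mutually observed
    samples, fewer than k donors) are left at zero and recorded in
    ``meta['non_imputable']`` as (taxon_id, reason) — rare taxa commonly fail
    here, which is itself diagnostic.
    """
    if k <= 0:
        raise ProfileError("k must be positive")
    vals = profile.values
    observed = vals > 0
    D, S = vals.shape

    # standardize each sample column on its observed entries for distances
    z = np.zeros_like(vals)
    for j in range(S):
        obs = observed[:, j]
        if obs.sum() >= 2:
            mu = vals[obs, j].mean()
            sd = vals[obs, j].std()
            z[obs, j] = (vals[obs, j] - mu) / (sd if sd > 0 else 1.0)
        elif obs.sum() == 1:
            z[obs, j] = 0.0

    # pairwise RMS distance over mutually observed entries
    obs_f = observed.astype(float)
    shared = obs_f @ obs_f.T                      # counts of mutually observed samples
    zz = (z * obs_f) @ (z * obs_f).T
    sq = ((z * obs_f) ** 2) @ obs_f.T
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = (sq + sq.T - 2.0 * zz) / shared
    msd = np.where(shared > 0, np.maximum(msd, 0.0), np.inf)
    dist = np.sqrt(msd)

    out = vals.copy()
    non_imputable: list[tuple[str, str]] = []
    for i in range(D):
        if not observed[i].any():
            non_imputable.append((profile.taxon_ids[i], "all values missing"))
            continue
        missing = np.flatnonzero(~observed[i])
        if missing.size == 0:
            continue
        failed = False
        for s in missing:
            donors = np.flatnonzero(observed[:, s] & np.isfinite(dist[i]))
            donors = donors[donors != i]
            if donors.size < k:
                failed = True
                continue
            order = donors[np.argsort(dist[i, donors], kind="stable")][:k]
            d = dist[i, order]
            w = np.exp(-(d ** 2) / (2.0 * bandwidth ** 2))
            if w.sum() <= 0:
                w = np.ones_like(w)
            out[i, s] = float(np.dot(w, vals[order, s]) / w.sum())
        if failed:
            non_imputable.append((profile.taxon_ids[i], f"fewer than k={k} donors"))
    if non_imputable:
        log.warning("knn_impute: %d taxa (partially) non-imputable", len(non_imputable))
    return AbundanceProfile(
        list(profile.taxon_ids), list(profile.sample_ids), out,
        {**profile.meta, "policy": 2, "knn_k": k, "state": "real",
         "non_imputable": non_imputable},
    )


def write_non_imputable_report(profile: AbundanceProfile, path: str | Path) -> None:
    """Write the kNN non-imputable taxon report (taxon ID, reason) as TSV."""
    rows = profile.meta.get("non_imputable", [])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\treason\n")
        for tid, reason in rows:
            fh.write(f"{tid}\t{reason}\n")


# -- pair-level filtering --------------------------------------------------


def pair_filter(
    x: Sequence[float],
    y: Sequence[float],
    policy: int | FilterPolicy,
    pseudo_value: float = 0.01,
    sample_ids: Sequence[str] | None = None,
    x_zero: np.ndarray | None = None,
    y_zero: np.ndarray | None = None,
) -> FilteredPair:
    """Apply a zero policy to one aligned taxon pair.

    ``x_zero`` / ``y_zero`` optionally supply the zero masks explicitly (used
    when correlating CLR-transformed values, whose zero pattern must be taken
    from the pre-transform counts); they default to ``x == 0`` / ``y == 0``.
    """
    code = policy.code if isinstance(policy, FilterPolicy) else int(policy)
    if isinstance(policy, FilterPolicy):
        pseudo_value = policy.pseudo_value
    if code not in POLICY_NAMES:
        raise ProfileError(f"unknown policy code {code}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ProfileError("x and y must be aligned 1-D vectors")
    n = len(x)
    ids = [str(s) for s in sample_ids] if sample_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ProfileError("sample_ids length mismatch")
    zx = np.asarray(x_zero, dtype=bool) if x_zero is not None else (x == 0)
    zy = np.asarray(y_zero, dtype=bool) if y_zero is not None else (y == 0)
    if zx.shape != x.shape or zy.shape != y.shape:
        raise ProfileError("zero-mask length mismatch")

    if code in (1, 2):
        keep = np.ones(n, dtype=bool)
        fx, fy = x[keep], y[keep]
    elif code == 3:
        keep = np.ones(n, dtype=bool)
        fx = np.where(zx, pseudo_value, x)
        fy = np.where(zy, pseudo_value, y)
    elif code in (4, 5):
        keep = ~(zx & zy)
        fx, fy = x[keep], y[keep]
        if code == 4:
            fx = np.where(zx[keep], pseudo_value, fx)
            fy = np.where(zy[keep], pseudo_value, fy)
    else:  # 6: complete cases only
        keep = ~(zx | zy)
        fx, fy = x[keep], y[keep]
    kept_ids = [s for s, m in zip(ids, keep) if m]
    return FilteredPair(fx, fy, kept_ids, int(keep.sum()))


def count_eligible_pairs(
    profile: AbundanceProfile,
    policy: int | FilterPolicy,
    min_overlap: int = 30,
) -> int:
    """Count unordered taxon pairs whose valid-sample count exceeds ``min_overlap``.

    The bound is strict (``n_valid > min_overlap``). Policies 1-3 keep every
    sample, so all C(D, 2) pairs are eligible whenever the profile has more
    than ``min_overlap`` samples.
    """
    code = policy.code if isinstance(policy, FilterPolicy) else int(policy)
    if code not in POLICY_NAMES:
        raise ProfileError(f"unknown policy code {code}")
    D, S = profile.shape
    if D < 2:
        return 0
    total = D * (D - 1) // 2
    if code in PROFILE_LEVEL:
        return total if S > min_overlap else 0
    present = (profile.values > 0)
    if code == 6:
        overlap = present.astype(np.int64) @ present.astype(np.int64).T
    else:  # 4 and 5 share the paired-zero drop rule
        absent = (~present).astype(np.int64)
        overlap = S - absent @ absent.T
    iu = np.triu_indices(D, k=1)
    return int(np.sum(overlap[iu] > min_overlap))
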