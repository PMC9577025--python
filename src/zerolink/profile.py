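"""Abundance-profile container and preprocessing.

Reads OTU-by-sample tab-separated tables, removes unwanted rows (e.g. an
"unclassified" aggregate), rarefies counts to a common sequencing depth,
filters taxa by sample-occurrence frequency, and applies the centered
log-ratio (CLR) transform used for compositional data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AbundanceProfile",
    "FrequencyBand",
    "ProfileError",
    "read_profile",
    "write_profile",
    "drop_taxon",
    "rarefy",
    "frequency_filter",
    "clr_transform",
]


class ProfileError(ValueError):
    """Raised when a profile violates its invariants or an operation's preconditions."""


@dataclass
class AbundanceProfile:
    """A taxon x sample abundance matrix with string identifiers.

    Parameters
    ----------
    taxon_ids : sequence of str
        Row identifiers (OTU / taxon names); must be unique.
    sample_ids : sequence of str
        Column identifiers (community / sample names); must be unique.
    values : ndarray of shape (n_taxa, n_samples)
        Non-negative abundances. Integer counts before any transform;
        real-valued after CLR (where columns are zero-centered instead).
    meta : dict
        Free-form provenance: source file, rarefaction depth, transform
        applied, counts/real state, warnings.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ProfileError("values must be a 2-D taxon x sample matrix")
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ProfileError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        dup_t = _duplicates(self.taxon_ids)
        if dup_t:
            raise ProfileError(f"duplicate taxon IDs: {sorted(dup_t)[:5]}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ProfileError(f"duplicate sample IDs: {sorted(dup_s)[:5]}")
        if self.meta.get("transform") is None and self.values.size and self.values.min() < 0:
            raise ProfileError("negative abundance values in an untransformed profile")

    # -- convenience -------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def zero_mask(self) -> np.ndarray:
        """Boolean matrix marking cells equal to zero (the missing-value sentinel)."""
        return self.values == 0

    def zero_fraction(self) -> float:
        if self.values.size == 0:
            raise ProfileError("zero fraction undefined for an empty profile")
        return float(np.mean(self.values == 0))

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxon_ids.index(label)
        except ValueError:
            raise ProfileError(f"taxon {label!r} not in profile") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)

    def copy(self, **meta_updates) -> "AbundanceProfile":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return AbundanceProfile(
            list(self.taxon_ids), list(self.sample_ids), self.values.copy(), meta
        )


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in ids:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


# -- I/O -------------------------------------------------------------------


def read_profile(path: str | Path, format: str = "tsv") -> AbundanceProfile:
    """Read a tab-separated abundance table.

    First row is the sample header, first column the taxon IDs, remaining
    cells numeric. Lines starting with ``#`` are skipped. Dimensions and the
    zero fraction are logged on success.
    """
    if format != "tsv":
        raise ProfileError(f"unsupported format {format!r}")
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0, header=0, dtype=str)
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ProfileError(
                    f"malformed numeric cell at taxon {frame.index[i]!r}, "
                    f"sample {col!r}: {raw!r}"
                ) from None
    is_counts = bool(values.size == 0 or np.all(values == np.round(values)))
    meta = {"source": str(path), "state": "counts" if is_counts else "real"}
    if values.size and values.min() < 0:
        # negative cells mean a transformed (e.g. CLR) table was read back
        meta["transform"] = "imported"
    prof = AbundanceProfile(list(frame.index), list(frame.columns), values, meta)
    if prof.values.size:
        log.info(
            "read %s: %d taxa x %d samples, zero fraction %.4f",
            path, prof.n_taxa, prof.n_samples, prof.zero_fraction(),
        )
    return prof


def write_profile(profile: AbundanceProfile, path: str | Path) -> None:
    """Write a profile as TSV; round-trips losslessly through :func:`read_profile`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\t" + "\t".join(profile.sample_ids) + "\n")
        for i, tid in enumerate(profile.taxon_ids):
            row = "\t".join(_fmt(v) for v in profile.values[i])
            fh.write(tid + ("\t" + row if profile.n_samples else "") + "\n")


def _fmt(v: float) -> str:
    # integers stay integers; reals keep full double precision
    if float(v).is_integer() and abs(v) < 2**53:
        return str(int(v))
    return repr(float(v))


# -- cleaning --------------------------------------------------------------


def drop_taxon(profile: AbundanceProfile, label: str, strict: bool = True) -> AbundanceProfile:
    """Remove one taxon row (e.g. an aggregate "unclassified" row).

    With ``strict=False`` a missing label only logs a warning and returns the
    profile unchanged.
    """
    if label not in profile.taxon_ids:
        if strict:
            raise ProfileError(f"taxon {label!r} not present")
        log.warning("drop_taxon: label %r absent, profile unchanged", label)
        return profile.copy()
    idx = profile.taxon_ids.index(label)
    keep = [i for i in range(profile.n_taxa) if i != idx]
    return AbundanceProfile(
        [profile.taxon_ids[i] for i in keep],
        list(profile.sample_ids),
        profile.values[keep],
        {**profile.meta, "dropped": profile.meta.get("dropped", []) + [label]},
    )


# -- rarefaction -----------------------------------------------------------


def rarefy(profile: AbundanceProfile, depth: int, seed: int) -> AbundanceProfile:
    """Subsample every sample to ``depth`` reads without replacement.

    Each sample column is drawn from a multivariate hypergeometric
    distribution over its taxon counts, so retained columns sum exactly to
    ``depth`` and no taxon exceeds its original count. Samples whose total is
    below ``depth`` are dropped with a logged warning. Deterministic given
    ``seed``.
    """
    if depth <= 0:
        raise ProfileError("rarefaction depth must be positive")
    vals = profile.values
    if vals.size and not np.all(vals == np.round(vals)):
        raise ProfileError("rarefy requires integer counts")
    counts = vals.astype(np.int64)
    totals = counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(profile.sample_ids, keep) if not k]
    if dropped:
        log.warning("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped[:5])
    rng = np.random.default_rng(seed)
    kept_ids = [s for s, k in zip(profile.sample_ids, keep) if k]
    out = np.zeros((profile.n_taxa, len(kept_ids)), dtype=np.int64)
    j_out = 0
    for j in range(profile.n_samples):
        if not keep[j]:
            continue
        col = counts[:, j]
        if totals[j] == depth:
            out[:, j_out] = col
        else:
            out[:, j_out] = rng.multivariate_hypergeometric(col, depth, method="marginals")
        j_out += 1
    return AbundanceProfile(
        list(profile.taxon_ids), kept_ids, out.astype(float),
        {**profile.meta, "rarefaction_depth": depth, "rarefaction_seed": seed,
         "state": "counts"},
    )


# -- frequency filtering ---------------------------------------------------


@dataclass(frozen=True)
class FrequencyBand:
    """Occurrence band: keep taxa present (value > 0) in between
    ``min_samples`` and ``max_samples`` samples inclusive."""

    min_samples: int = 0
    max_samples: float = math.inf

    def __post_init__(self) -> None:
        if self.min_samples < 0:
            raise ProfileError("min_samples must be >= 0")
        if self.min_samples > self.max_samples:
            raise ProfileError("min_samples must not exceed max_samples")


def frequency_filter(profile: AbundanceProfile, band: FrequencyBand) -> AbundanceProfile:
    """Retain taxa whose presence count (samples with value > 0) lies in ``band``."""
    presence = (profile.values > 0).sum(axis=1)
    keep = [i for i in range(profile.n_taxa)
            if band.min_samples <= presence[i] <= band.max_samples]
    log.info("frequency_filter: kept %d / %d taxa in band [%s, %s]",
             len(keep), profile.n_taxa, band.min_samples, band.max_samples)
    return AbundanceProfile(
        [profile.taxon_ids[i] for i in keep],
        list(profile.sample_ids),
        profile.values[keep],
        {**profile.meta, "frequency_band": (band.min_samples, band.max_samples)},
    )


# -- centered log-ratio ----------------------------------------------------


def clr_transform(profile: AbundanceProfile, pseudocount: float | None = None) -> AbundanceProfile:
    """Centered log-ratio transform, per sample column (natural log).

    ``y_j = log(x_j) - mean(log(x_j))`` for each sample. Zeros must already
    have been handled: either a filtering policy replaced them upstream
    (``pseudocount=None``), or ``pseudocount`` > 0 is added to every zero
    cell here. Any non-positive value reaching the log raises, naming the
    offending cell.
    """
    vals = profile.values.copy()
    if pseudocount is not None:
        if pseudocount <= 0:
            raise ProfileError("pseudocount must be > 0")
        vals[vals == 0] = pseudocount
    bad = np.argwhere(vals <= 0)
    if bad.size:
        i, j = bad[0]
        raise ProfileError(
            f"non-positive value at taxon {profile.taxon_ids[i]!r}, "
            f"sample {profile.sample_ids[j]!r}; fill zeros before CLR"
        )
    logv = np.log(vals)
    clr = logv - logv.mean(axis=0, keepdims=True)
    return AbundanceProfile(
        list(profile.taxon_ids), list(profile.sample_ids), clr,
        {**profile.meta, "transform": "clr", "state": "real"},
    )
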