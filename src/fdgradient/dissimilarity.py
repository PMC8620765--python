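"""Pairwise dissimilarities: species-level trait distances and plot-level
floristic distances.

The species x species matrix feeds Rao's quadratic entropy; by
construction its entries lie in [0, 1], with 0 for identical trait
profiles and 1 for maximally different ones.  Mixed trait types
(continuous, ordinal, categorical) are handled with Gower's coefficient:

* continuous — |x_i - x_j| / range, after the declared transform, with
  the range taken over the full species pool so every plot shares the
  same d_ij;
* ordinal — Podani's (1999) rank-based extension, which uses tie-corrected
  ranks instead of treating ordered category codes as measurements;
* categorical — simple mismatch (0 same level, 1 different).

Per-pair averaging uses only traits observed in both species (pairwise
deletion); missing values are never imputed.

Plot x plot distances use Bray-Curtis on untransformed percent cover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io_data import CoverMatrix, TraitSet, TraitTable, ValidationError

logger = logging.getLogger("fdgradient")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise distance matrix with labelled ids."""

    ids: tuple[str, ...]
    values: np.ndarray
    scale_note: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("dissimilarity matrix shape does not match ids")
        if not np.isfinite(v).all():
            raise ValidationError("non-finite dissimilarity entries")
        if (v < 0).any():
            raise ValidationError("negative dissimilarity entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity diagonal is not zero")
        self.values = v

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def submatrix(self, ids) -> "DissimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DissimilarityMatrix(
            tuple(ids), self.values[np.ix_(idx, idx)], self.scale_note
        )


def _continuous_part(col: np.ndarray, transform: str, trait: str):
    """Per-pair |x_i - x_j| / pool range; zero-range traits contribute 0."""
    x = col.astype(float)
    obs = np.isfinite(x)
    y = np.where(obs, x, np.nan)
    if transform == "log10":
        y = np.log10(y)
    lo, hi = np.nanmin(y), np.nanmax(y)
    rng = hi - lo
    if rng <= 0:
        logger.warning("trait %r has zero range; it contributes 0 to all pairs", trait)
        part = np.zeros((len(x), len(x)))
    else:
        part = np.abs(y[:, None] - y[None, :]) / rng
    return part, obs


def _ordinal_part(col, levels: tuple[str, ...], trait: str):
    """Podani's tie-corrected rank dissimilarity for ordered categories.

    d_ij = (|r_i - r_j| - (T_i - 1)/2 - (T_j - 1)/2)
           / (r_max - r_min - (T_max - 1)/2 - (T_min - 1)/2)

    with r the mean ranks of the observed values, T_i the number of
    species tied with i, and T_max/T_min the tie counts at the extreme
    observed values; d_ij = 0 for species sharing a level.
    """
    codes = np.array(
        [levels.index(v) if isinstance(v, str) else -1 for v in col], dtype=float
    )
    obs = codes >= 0
    n = len(codes)
    part = np.zeros((n, n))
    if obs.sum() >= 2:
        r = np.full(n, np.nan)
        r[obs] = rankdata(codes[obs])
        tie = np.zeros(n)
        for lev in np.unique(codes[obs]):
            mask = obs & (codes == lev)
            tie[mask] = mask.sum()
        rmin, rmax = np.nanmin(r), np.nanmax(r)
        t_at_min = tie[obs][np.argmin(r[obs])]
        t_at_max = tie[obs][np.argmax(r[obs])]
        denom = rmax - rmin - (t_at_max - 1) / 2 - (t_at_min - 1) / 2
        if denom <= 0:
            logger.warning(
                "ordinal trait %r has a single observed level; contributes 0", trait
            )
        else:
            num = (
                np.abs(r[:, None] - r[None, :])
                - (tie[:, None] - 1) / 2
                - (tie[None, :] - 1) / 2
            )
            part = np.clip(num / denom, 0.0, 1.0)
            same = codes[:, None] == codes[None, :]
            part[same] = 0.0
    return part, obs


def _categorical_part(col):
    vals = np.array([v if isinstance(v, str) else None for v in col], dtype=object)
    obs = np.array([v is not None for v in vals])
    part = (vals[:, None] != vals[None, :]).astype(float)
    return part, obs


def gower_dissimilarity(traits: TraitTable, trait_set: TraitSet) -> DissimilarityMatrix:
    """Gower dissimilarity among all species over the traits in ``trait_set``.

    Ranges (and ordinal ranks) are computed over the full species pool in
    ``traits`` so the resulting d_ij does not depend on which plot the
    pair co-occurs in.  A species pair with no mutually observed trait in
    the set is an error.
    """
    missing = [t for t in trait_set.trait_ids if t not in traits.values.columns]
    if missing:
        raise ValidationError(f"trait set {trait_set.name!r} needs missing traits {missing}")
    species = list(traits.values.index)
    n = len(species)
    num = np.zeros((n, n))
    wsum = np.zeros((n, n))
    for trait in trait_set.trait_ids:
        meta = traits.trait_meta[trait]
        col = traits.values[trait].to_numpy()
        if meta.kind == "continuous":
            part, obs = _continuous_part(col, meta.transform, trait)
        elif meta.kind == "ordinal":
            part, obs = _ordinal_part(col, tuple(meta.levels), trait)
        else:
            part, obs = _categorical_part(col)
        w = np.outer(obs, obs).astype(float)
        num += np.where(w > 0, part, 0.0) * w
        wsum += w
    uncovered = wsum == 0
    np.fill_diagonal(uncovered, False)
    if uncovered.any():
        i, j = np.argwhere(uncovered)[0]
        raise ValidationError(
            f"species pair ({species[i]!r}, {species[j]!r}) shares no observed "
            f"trait in set {trait_set.name!r}"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(
        tuple(species),
        d,
        scale_note=(
            "Gower; continuous traits range-scaled over the full species pool "
            "(after declared transforms), ordinal traits Podani rank-standardized, "
            "categorical 0/1 mismatch; pairwise deletion of missing traits"
        ),
    )


def bray_curtis(cover: CoverMatrix) -> DissimilarityMatrix:
    """Bray-Curtis distances between plots on untransformed percent cover.

    BC(x, y) = sum|x_k - y_k| / sum(x_k + y_k); a pair of all-zero plots
    is assigned distance 0 with a warning.
    """
    x = cover.cover.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("Bray-Curtis needs at least 2 plots")
    totals = x.sum(axis=1)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    both_zero = (totals[:, None] == 0) & (totals[None, :] == 0)
    if (both_zero & ~np.eye(len(totals), dtype=bool)).any():
        logger.warning("all-zero plot pair(s): Bray-Curtis set to 0")
        d[both_zero] = 0.0
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(
        tuple(cover.plot_ids), d, scale_note="Bray-Curtis on untransformed percent cover"
    )
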