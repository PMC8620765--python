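"""Trait-shuffling null model and standardized effect size (SES).

The null hypothesis is random assembly with respect to traits: trait
values are shuffled among the species of the pool (999 times by default)
while the species composition matrix stays untouched, and the observed
functional diversity of each plot is standardized against the resulting
null distribution:

    SES = (I_obs - mean(I_sim)) / sd(I_sim)

Positive SES indicates trait divergence (limiting similarity), negative
SES trait convergence (filtering / competitive exclusion), values near
zero random assembly.

Two shuffle schemes are provided.  ``rows_joint`` permutes whole species
rows of the trait table (preserving inter-trait correlation) and is the
default for multi-trait sets; ``per_column`` permutes each trait column
independently and is the default for single-trait sets (for one column
the two schemes coincide).  Either way each trait's multiset of values is
exactly preserved.

Implementation note: relabelling species rows permutes the precomputed
trait dissimilarity matrix (d'_ij = d_{pi(i) pi(j)}), including the
missing-data pattern, so the null loop indexes one Gower matrix per trait
set instead of rebuilding it — the generic rebuild path is kept only for
the per-column scheme on multi-trait sets, where the identity does not
hold.  One shuffled trait matrix per iteration is applied to all plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissimilarity import gower_dissimilarity
from .fdiversity import exclude_focal
from .io_data import (
    CoverMatrix,
    TraitSet,
    TraitTable,
    ValidationError,
    align_cover_traits,
    canonical_trait_sets,
)

logger = logging.getLogger("fdgradient")


@dataclass
class NullConfig:
    """Settings for the trait-shuffle null.

    ``pool="regional"`` shuffles one species x trait matrix over all
    species (focal excluded); ``"per_transect"`` restricts each shuffle to
    the species observed in that transect.  ``standardize`` selects
    whether the Jost-corrected or the raw Rao value is standardized.
    """

    n_permutations: int = 999
    shuffle_scheme: str = "auto"  # auto | rows_joint | per_column
    pool: str = "regional"  # regional | per_transect
    seed: int = 0
    standardize: str = "jost"  # jost | raw

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.shuffle_scheme not in ("auto", "rows_joint", "per_column"):
            raise ValidationError(f"unknown shuffle scheme {self.shuffle_scheme!r}")
        if self.pool not in ("regional", "per_transect"):
            raise ValidationError(f"unknown pool {self.pool!r}")
        if self.standardize not in ("jost", "raw"):
            raise ValidationError(f"unknown standardize option {self.standardize!r}")


def shuffle_traits(traits: TraitTable, scheme: str, rng: np.random.Generator) -> TraitTable:
    """Return a trait table with values shuffled among species.

    ``rows_joint`` permutes complete species rows; ``per_column``
    permutes each trait column independently.  Species ids stay in place;
    only the trait values move.
    """
    vals = traits.values.copy()
    n = len(vals)
    if scheme == "rows_joint":
        perm = rng.permutation(n)
        vals.iloc[:, :] = traits.values.to_numpy(dtype=object)[perm]
    elif scheme == "per_column":
        for col in vals.columns:
            perm = rng.permutation(n)
            vals[col] = traits.values[col].to_numpy(dtype=object)[perm]
    else:
        raise ValidationError(f"unknown shuffle scheme {scheme!r}")
    return TraitTable(vals, dict(traits.trait_meta))


def _quad_form(P: np.ndarray, D: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Rao Q per plot for abundance rows P, masking invalid species."""
    Pm = P * valid
    rs = Pm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Pm = np.where(rs > 0, Pm / np.where(rs > 0, rs, 1.0), 0.0)
    return ((Pm @ D) * Pm).sum(axis=1)


def _resolve_scheme(config_scheme: str, trait_set: TraitSet) -> str:
    if config_scheme != "auto":
        return config_scheme
    return "rows_joint" if len(trait_set.trait_ids) > 1 else "per_column"


def ses_for_plots(
    cover: CoverMatrix,
    traits: TraitTable,
    focal_species_id: str,
    trait_sets: list[TraitSet] | None = None,
    config: NullConfig | None = None,
    permutations: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """SES per plot x trait set against the trait-shuffle null.

    Plots with fewer than two coexisting species carrying the set's
    traits are excluded (SES is undefined there); a zero-variance null
    sets the ``degenerate`` flag instead of raising.  ``permutations``
    overrides random sampling with an explicit list of pool-index
    permutations (applied as joint row shuffles), used for exhaustive
    small-pool enumeration.
    """
    config = config or NullConfig()
    trait_sets = trait_sets if trait_sets is not None else canonical_trait_sets()
    snapshot = cover.cover.to_numpy(dtype=float).copy()

    cover_a, traits_a = align_cover_traits(cover, traits, focal_species_id)
    pool_species = [s for s in traits_a.species_ids if s != focal_species_id]
    traits_pool = traits_a.subset_species(pool_species)
    S = len(pool_species)
    sp_index = {s: i for i, s in enumerate(pool_species)}

    plots = [pa for pa in exclude_focal(cover_a, focal_species_id) if not pa.empty]
    if not plots:
        raise ValidationError("no plots with coexisting species")
    P = np.zeros((len(plots), S))
    for r, pa in enumerate(plots):
        for s, w in zip(pa.species_ids, pa.p):
            P[r, sp_index[s]] = w
    plot_ids = [pa.plot_id for pa in plots]

    # species pools per shuffle group: one regional group, or one per transect
    if config.pool == "regional":
        groups = [(np.arange(len(plots)), np.arange(S))]
    else:
        meta = cover_a.plot_meta
        groups = []
        for _, plot_idx in pd.Series(
            range(len(plots)), index=plot_ids
        ).groupby(meta.loc[plot_ids, "transect_id"]):
            rows = plot_idx.to_numpy()
            pool_idx = np.flatnonzero(P[rows].sum(axis=0) > 0)
            groups.append((rows, pool_idx))

    # pre-draw permutations: one shuffled trait matrix per iteration
    rng = np.random.default_rng(config.seed)
    if permutations is not None:
        n_perm = len(permutations)
        joint = [
            [np.asarray(p, dtype=int) for p in permutations] for _ in groups
        ]
        cols: list[dict[str, list[np.ndarray]]] = [
            {t: jg for t in traits_pool.trait_ids} for jg in joint
        ]
    else:
        n_perm = config.n_permutations
        joint = [[] for _ in groups]
        cols = [{t: [] for t in traits_pool.trait_ids} for _ in groups]
        for _ in range(n_perm):
            for gi, (_, pool_idx) in enumerate(groups):
                full = np.arange(S)
                full[pool_idx] = pool_idx[rng.permutation(len(pool_idx))]
                joint[gi].append(full)
                for t in traits_pool.trait_ids:
                    full_c = np.arange(S)
                    full_c[pool_idx] = pool_idx[rng.permutation(len(pool_idx))]
                    cols[gi][t].append(full_c)

    def transform(q: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 - q) if config.standardize == "jost" else q

    records = []
    for ts in trait_sets:
        scheme = _resolve_scheme(config.shuffle_scheme, ts)
        fast = scheme == "rows_joint" or len(ts.trait_ids) == 1
        D = gower_dissimilarity(traits_pool, ts).values
        valid = (
            traits_pool.values[list(ts.trait_ids)].notna().any(axis=1).to_numpy()
        )
        n_sp = ((P > 0) & valid).sum(axis=1)
        keep = n_sp >= 2
        if not keep.all():
            logger.info(
                "trait set %r: excluding %d plot(s) with < 2 trait-bearing species",
                ts.name,
                int((~keep).sum()),
            )
        i_obs = transform(_quad_form(P, D, valid))

        sims = np.empty((n_perm, len(plots)))
        if fast:
            for k in range(n_perm):
                q = np.empty(len(plots))
                for gi, (rows, _) in enumerate(groups):
                    if scheme == "rows_joint":
                        perm = joint[gi][k]
                    else:  # per_column on a singleton set
                        perm = cols[gi][ts.trait_ids[0]][k]
                    Dp = D[np.ix_(perm, perm)]
                    q[rows] = _quad_form(P[rows], Dp, valid[perm])
                sims[k] = transform(q)
        else:
            # per_column on a multi-trait set: rebuild the Gower matrix
            for k in range(n_perm):
                q = np.empty(len(plots))
                for gi, (rows, _) in enumerate(groups):
                    vals = traits_pool.values.copy()
                    for t in ts.trait_ids:
                        perm = cols[gi][t][k]
                        vals[t] = traits_pool.values[t].to_numpy(dtype=object)[perm]
                    tt = TraitTable(vals, dict(traits_pool.trait_meta))
                    Dk = gower_dissimilarity(tt, ts).values
                    vk = tt.values[list(ts.trait_ids)].notna().any(axis=1).to_numpy()
                    q[rows] = _quad_form(P[rows], Dk, vk)
                sims[k] = transform(q)

        null_mean = sims.mean(axis=0)
        null_sd = sims.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(len(plots))
        degenerate = null_sd <= 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            ses = np.where(degenerate, np.nan, (i_obs - null_mean) / np.where(degenerate, 1.0, null_sd))
        for r in range(len(plots)):
            if not keep[r]:
                continue
            records.append(
                {
                    "plot_id": plot_ids[r],
                    "trait_set": ts.name,
                    "n_species": int(n_sp[r]),
                    "i_obs": i_obs[r],
                    "null_mean": null_mean[r],
                    "null_sd": null_sd[r],
                    "ses": ses[r],
                    "n_valid_perms": n_perm,
                    "degenerate": bool(degenerate[r]),
                }
            )

    assert np.array_equal(
        snapshot, cover.cover.to_numpy(dtype=float)
    ), "composition matrix was modified during null generation"
    return pd.DataFrame.from_records(records)
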