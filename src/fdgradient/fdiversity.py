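"""Per-plot functional diversity: Rao's quadratic entropy with the Jost
equivalent-number correction.

Rao's Q is the expected trait dissimilarity between two individuals drawn
(with replacement) from an assemblage:

    Q = sum_i sum_j d_ij p_i p_j

with p the relative abundances and d_ij in [0, 1] (d_ii = 0).  Because
the question is how the dominant species shapes the diversity of the
species coexisting *with* it, the focal dominant is removed from the
composition matrix first and abundances are renormalized over the
remaining assemblage.  The Jost correction 1/(1 - Q) converts Q into the
equivalent number of equally abundant, maximally distinct species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityMatrix, gower_dissimilarity
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
class PlotAbundance:
    """Relative abundances of the coexisting (focal-excluded) assemblage."""

    plot_id: str
    species_ids: tuple[str, ...]
    p: np.ndarray
    empty: bool = False

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.n_species:
            if abs(self.p.sum() - 1.0) > 1e-12:
                raise ValidationError(
                    f"abundances of plot {self.plot_id!r} sum to {self.p.sum()}, not 1"
                )
            if (self.p <= 0).any():
                raise ValidationError(f"non-positive abundance in plot {self.plot_id!r}")


def exclude_focal(cover: CoverMatrix, focal_species_id: str) -> list[PlotAbundance]:
    """Drop the focal species column and renormalize covers to proportions.

    Plots left with no coexisting species are carried, flagged ``empty``,
    rather than dropped: downstream stages decide what to do with them.
    """
    if focal_species_id not in cover.cover.columns:
        raise ValidationError(f"unknown focal species {focal_species_id!r}")
    sub = cover.cover.drop(columns=[focal_species_id])
    out: list[PlotAbundance] = []
    for plot_id, row in sub.iterrows():
        vals = row.to_numpy(dtype=float)
        present = vals > 0
        total = vals[present].sum()
        if total <= 0:
            out.append(PlotAbundance(str(plot_id), (), np.array([]), empty=True))
        else:
            sp = tuple(sub.columns[present])
            out.append(PlotAbundance(str(plot_id), sp, vals[present] / total))
    return out


def rao_q(pa: PlotAbundance, D: DissimilarityMatrix) -> float:
    """Rao's quadratic entropy Q = p' D p for one assemblage."""
    if pa.n_species <= 1:
        return 0.0
    missing = [s for s in pa.species_ids if s not in D.ids]
    if missing:
        raise ValidationError(f"species {missing} absent from dissimilarity matrix")
    idx = np.fromiter((D.ids.index(s) for s in pa.species_ids), dtype=int)
    d = D.values[np.ix_(idx, idx)]
    return float(pa.p @ d @ pa.p)


def jost_correct(q_raw: float) -> float:
    """Equivalent number of maximally distinct species: 1 / (1 - Q)."""
    if not 0.0 <= q_raw < 1.0:
        raise ValidationError(f"Rao Q must lie in [0, 1); got {q_raw}")
    return 1.0 / (1.0 - q_raw)


def fd_per_plot(
    cover: CoverMatrix,
    traits: TraitTable,
    focal_species_id: str,
    trait_sets: list[TraitSet] | None = None,
) -> pd.DataFrame:
    """Rao's Q (raw and Jost-corrected) per plot x trait set.

    Species missing every trait of a given set are dropped from that
    set's computation for the affected plots, with renormalized
    abundances and a warning.  Returns one row per plot x trait set with
    columns plot_id, trait_set, q_raw, q_jost, n_species.
    """
    if trait_sets is None:
        trait_sets = canonical_trait_sets()
    cover, traits = align_cover_traits(cover, traits, focal_species_id)
    # the focal species never enters the coexisting assemblages, so it is
    # kept out of the trait pool too (range scaling, ordinal ranks)
    traits = traits.subset_species(
        [s for s in traits.species_ids if s != focal_species_id]
    )
    plots = exclude_focal(cover, focal_species_id)
    rows = []
    for ts in trait_sets:
        D = gower_dissimilarity(traits, ts)
        observed = traits.values[list(ts.trait_ids)].notna().any(axis=1)
        valid = set(observed.index[observed])
        dropped_any = False
        for pa in plots:
            keep = [i for i, s in enumerate(pa.species_ids) if s in valid]
            if len(keep) < pa.n_species:
                dropped_any = True
            if pa.empty or not keep:
                rows.append((pa.plot_id, ts.name, 0.0, 1.0, 0))
                continue
            p = pa.p[keep] / pa.p[keep].sum()
            sub = PlotAbundance(pa.plot_id, tuple(pa.species_ids[i] for i in keep), p)
            q = rao_q(sub, D)
            rows.append((pa.plot_id, ts.name, q, jost_correct(q), sub.n_species))
        if dropped_any:
            logger.warning(
                "trait set %r: some species lacked all traits of the set and were "
                "dropped from affected plots (abundances renormalized)",
                ts.name,
            )
    return pd.DataFrame(rows, columns=["plot_id", "trait_set", "q_raw", "q_jost", "n_species"])
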