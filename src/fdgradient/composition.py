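"""Floristic composition: ANOSIM between site types and NMDS ordination.

ANOSIM ranks all n(n-1)/2 pairwise Bray-Curtis distances (mean ranks on
ties) and contrasts mean between-group vs within-group ranks:

    R = (rbar_between - rbar_within) / (M / 2),  M = n(n-1)/2

R near 0 means the groups are floristically similar, near 1 strongly
dissimilar; the theoretical range is [-1, 1] and negative observed
values are reported as computed.  The one-sided permutation p-value
(label shuffles, R_perm >= R_obs) uses the add-one correction
p = (1 + #exceedances) / (1 + n_permutations).

NMDS embeds the plots so that configuration distances are monotone in
the input dissimilarities, minimizing Kruskal stress-1 via iterative
majorization with isotonic regression; the optimizer is the established
SMACOF routine, seeded from a classical-scaling start plus random
restarts.  Coordinates are centered and rotated onto principal axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .dissimilarity import DissimilarityMatrix
from .io_data import ValidationError

logger = logging.getLogger("fdgradient")


@dataclass
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # plots x k axes
    stress: float  # Kruskal stress-1
    converged: bool
    n_starts: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    D: DissimilarityMatrix,
    groups,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> AnosimResult:
    """Analysis of similarities on a plot dissimilarity matrix.

    ``groups`` maps each plot (in D order) to its group label; every
    group needs at least two members.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    labels = np.asarray(pd.Series(list(groups)).to_numpy())
    if len(labels) != len(D.ids):
        raise ValidationError("group labels do not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs >= 2 groups")
    if counts.min() < 2:
        small = uniq[counts.argmin()]
        raise ValidationError(f"group {small!r} has fewer than 2 members")
    rng = rng or np.random.default_rng()

    condensed = squareform(D.values, checks=False)
    ranks = rankdata(condensed)  # mean ranks on ties
    iu, ju = np.triu_indices(len(labels), k=1)
    within = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, within)

    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        r_perm = _anosim_r(ranks, perm[iu] == perm[ju])
        if r_perm >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return AnosimResult(
        r_statistic=r_obs,
        p_value=p,
        n_permutations=n_permutations,
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
    )


def kruskal_stress1(D: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities.

    Fits the monotone (isotonic) regression of configuration distances on
    the input dissimilarities and returns
    sqrt(sum (d - dhat)^2 / sum d^2) over all pairs.
    """
    dis = squareform(D, checks=False)
    dist = pdist(coords)
    order = np.argsort(dis, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(dist)
    dhat[order] = iso.fit_transform(np.arange(len(dis)), dist[order])
    denom = (dist**2).sum()
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    L = np.sqrt(np.clip(w[idx], 0, None))
    return v[:, idx] * L


def nmds(
    D: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 4,
    rng: np.random.Generator | None = None,
    max_iter: int = 300,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling to k axes.

    Runs SMACOF with a classical-scaling initialization plus
    ``n_starts - 1`` random restarts and keeps the configuration with the
    lowest Kruskal stress-1.  Axes are centered, principal-axis rotated
    and sign-fixed for determinism.
    """
    if k < 1 or n_starts < 1:
        raise ValidationError("k and n_starts must be >= 1")
    rng = rng or np.random.default_rng()
    dmat = D.values
    best = None
    for s in range(n_starts):
        if s == 0:
            init = _classical_mds(dmat, k)
        else:
            init = rng.normal(size=(len(dmat), k))
        seed = int(rng.integers(0, 2**31 - 1))
        coords, _, n_iter = smacof(
            dmat,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=1e-9,
            normalized_stress=True,
            random_state=seed,
            return_n_iter=True,
        )
        stress = kruskal_stress1(dmat, coords)
        converged = n_iter < max_iter
        if best is None or stress < best[0]:
            best = (stress, coords, converged)
    stress, coords, converged = best
    if not converged:
        logger.warning("NMDS did not converge within %d iterations", max_iter)
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for j in range(coords.shape[1]):  # deterministic sign
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    frame = pd.DataFrame(
        coords, index=list(D.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    frame.index.name = "plot_id"
    return OrdinationResult(frame, stress, converged, n_starts)
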