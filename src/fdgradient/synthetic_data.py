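"""Synthetic transect datasets with known assembly regimes.

The generator emulates the study design that motivates the pipeline: six
20-plot transects of 2 x 1 m quadrat couplets, each running from absence
of the focal dominant at the start, through a transition zone, to a
monodominant stand at the end; two site types whose transects carry
disjoint subordinate marker species at the transect start.  On top of
that design template it adds what field data cannot offer — ground
truth: the per-plot assembly regime is a knob.

* ``random`` — coexisting species drawn uniformly from the pool;
* ``convergent`` — species drawn with probability decaying in trait
  distance to a plot anchor (environmental filtering / competitive
  exclusion analogue);
* ``divergent`` — sequential selection penalizing trait similarity to
  already-selected species (limiting-similarity kernel).

Regime pressure is sharpened with focal cover, so the trait signal
concentrates where the dominant dominates.  Coexisting richness shrinks
mildly with focal cover (Poisson), mimicking monodominance without
hard-coding the diversity outcome — richness effects on raw Rao Q are
exactly what the SES null is meant to absorb.

Trait distributions are loosely parameterized on temperate-herb orders
of magnitude; they exist to give Gower distances non-degenerate
structure, not to claim realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dissimilarity import gower_dissimilarity
from .io_data import (
    CANONICAL_TRAITS,
    CoverMatrix,
    TraitMeta,
    TraitSet,
    TraitTable,
    ValidationError,
)

logger = logging.getLogger("fdgradient")

PCGO_LEVELS = ("<1yr", "1-2yr", ">2yr")
NCO_LEVELS = ("1", "2-10", ">10")


def default_trait_model() -> dict:
    """Per-trait sampling distributions (units in the metadata)."""
    return {
        "H": {"dist": "lognormal", "meanlog": np.log(0.35), "sdlog": 0.6,
              "units": "m", "transform": "log10"},
        "LDMC": {"dist": "normal", "mean": 250.0, "sd": 60.0, "min": 60.0,
                 "units": "mg/g", "transform": "none"},
        "LA": {"dist": "lognormal", "meanlog": np.log(1500.0), "sdlog": 1.0,
               "units": "mm2", "transform": "log10"},
        "SM": {"dist": "lognormal", "meanlog": 0.0, "sdlog": 1.2,
               "units": "mg", "transform": "log10"},
        "LS": {"dist": "lognormal", "meanlog": np.log(0.08), "sdlog": 0.9,
               "units": "m/yr", "transform": "none"},
        "PCGO": {"dist": "ordinal", "levels": PCGO_LEVELS, "probs": (0.3, 0.4, 0.3),
                 "units": "category", "transform": "none"},
        "NCO": {"dist": "ordinal", "levels": NCO_LEVELS, "probs": (0.4, 0.4, 0.2),
                "units": "category", "transform": "none"},
    }


@dataclass
class SimConfig:
    """Design and regime settings for one synthetic dataset.

    Defaults reproduce the study's design scale: 6 transects x 20 plots
    = 120 plots, two site types with disjoint subordinate marker species
    (20% of the pool unique per type).
    """

    n_transects: int = 6
    plots_per_transect: int = 20
    n_species_pool: int = 40
    site_types: tuple[str, str] = ("type_A", "type_B")
    focal_ramp: str = "logistic"  # linear | logistic
    assembly_regime: str = "random"  # random | convergent | divergent
    regime_strength: float = 1.0
    trait_model: dict = field(default_factory=default_trait_model)
    noise_sd: float = 0.15
    mean_richness: float = 12.0
    marker_fraction: float = 0.2
    focal_species_id: str = "focal_dominant"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.regime_strength <= 1.0:
            raise ValidationError("regime_strength must lie in [0, 1]")
        if self.assembly_regime not in ("random", "convergent", "divergent"):
            raise ValidationError(f"unknown regime {self.assembly_regime!r}")
        if self.focal_ramp not in ("linear", "logistic"):
            raise ValidationError(f"unknown focal ramp {self.focal_ramp!r}")


@dataclass
class SyntheticDataset:
    cover: CoverMatrix
    traits: TraitTable
    truth: dict


def _ramp(config: SimConfig, pos: np.ndarray) -> np.ndarray:
    last = config.plots_per_transect - 1
    if config.focal_ramp == "linear":
        return 100.0 * pos / last
    return 100.0 / (1.0 + np.exp(-0.7 * (pos - last / 2.0)))


def _draw_traits(config: SimConfig, species: list[str], rng) -> TraitTable:
    model = config.trait_model
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, TraitMeta] = {}
    n = len(species)
    for trait in CANONICAL_TRAITS:
        spec = model[trait]
        if spec["dist"] == "lognormal":
            cols[trait] = np.exp(rng.normal(spec["meanlog"], spec["sdlog"], n))
            kind, levels = "continuous", None
        elif spec["dist"] == "normal":
            vals = rng.normal(spec["mean"], spec["sd"], n)
            cols[trait] = np.maximum(vals, spec.get("min", -np.inf))
            kind, levels = "continuous", None
        elif spec["dist"] == "ordinal":
            levels = tuple(spec["levels"])
            cols[trait] = rng.choice(levels, size=n, p=spec["probs"])
            kind = "ordinal"
        else:
            raise ValidationError(f"unknown trait distribution {spec['dist']!r}")
        meta[trait] = TraitMeta(
            kind=kind,
            units=spec.get("units", ""),
            transform=spec.get("transform", "none"),
            levels=levels,
        )
    df = pd.DataFrame(cols, index=species)
    return TraitTable(df, meta)


def _select_species(
    regime: str,
    strength: float,
    candidates: np.ndarray,
    k: int,
    D: np.ndarray,
    rng: np.random.Generator,
    prior: np.ndarray | None = None,
) -> list[int]:
    """Pick k species (pool indices) under the assembly regime.

    ``prior`` holds trait-independent selection weights per candidate
    (the site-type affinity of its subordinate flora); the regime kernel
    multiplies it.
    """
    cand = list(candidates)
    pw = list(prior if prior is not None else np.ones(len(cand)))
    k = min(k, len(cand))
    selected: list[int] = []
    if regime == "random" or strength <= 0:
        w = np.asarray(pw) / np.sum(pw)
        return list(rng.choice(cand, size=k, replace=False, p=w))
    lam = 14.0 * strength
    if regime == "convergent":
        anchor = int(rng.choice(cand))
        for _ in range(k):
            d = D[anchor, cand]
            w = np.exp(-lam * d) * np.asarray(pw)
            w /= w.sum()
            pick = rng.choice(len(cand), p=w)
            selected.append(cand.pop(pick))
            pw.pop(pick)
    else:  # divergent: limiting-similarity kernel
        pick = rng.integers(len(cand))
        selected.append(cand.pop(pick))
        pw.pop(pick)
        for _ in range(k - 1):
            mind = np.min(D[np.ix_(selected, cand)], axis=0)
            w = np.exp(lam * (mind - mind.max())) * np.asarray(pw)
            w /= w.sum()
            pick = rng.choice(len(cand), p=w)
            selected.append(cand.pop(pick))
            pw.pop(pick)
    return selected


def generate(config: SimConfig) -> SyntheticDataset:
    """Draw one synthetic transect dataset with ground-truth labels."""
    rng = np.random.default_rng(config.seed)
    n = config.n_species_pool
    n_marker = max(1, int(round(config.marker_fraction * n)))
    pool = [f"sp{i + 1:03d}" for i in range(n)]
    assignment = {}
    for i, sp in enumerate(pool):
        if i < n_marker:
            assignment[sp] = "unique_" + config.site_types[0]
        elif i < 2 * n_marker:
            assignment[sp] = "unique_" + config.site_types[1]
        else:
            assignment[sp] = "shared"
    markers = {config.site_types[0]: pool[0], config.site_types[1]: pool[n_marker]}

    traits = _draw_traits(config, pool + [config.focal_species_id], rng)
    traits_pool = traits.subset_species(pool)
    D = gower_dissimilarity(traits_pool, TraitSet("Multiple", CANONICAL_TRAITS)).values

    type_of = {
        f"T{t + 1}": config.site_types[t % 2] for t in range(config.n_transects)
    }
    # candidates per site type, with an affinity prior: the type's own
    # subordinate species are a few times likelier to be drawn, so types
    # stay floristically distinct along the whole transect
    cand_idx = {
        st: np.array(
            [
                i
                for i, sp in enumerate(pool)
                if assignment[sp] in ("shared", "unique_" + st)
            ]
        )
        for st in config.site_types
    }
    cand_prior = {
        st: np.array(
            [
                4.0 if assignment[pool[i]] == "unique_" + st else 1.0
                for i in cand_idx[st]
            ]
        )
        for st in config.site_types
    }

    species_cols = [config.focal_species_id] + pool
    rows, meta_rows, plot_ids = [], [], []
    focal_curve: dict[str, float] = {}
    strength_eff_per_plot: dict[str, float] = {}
    pos = np.arange(config.plots_per_transect)
    for transect, st in type_of.items():
        base = _ramp(config, pos)
        noisy = base * np.exp(config.noise_sd * 0.5 * rng.normal(size=len(pos)))
        c_t = np.minimum(np.maximum.accumulate(noisy), 100.0)
        c_t[0] = base[0]
        c_t[-1] = max(c_t[-1], 92.0)
        marker_idx = pool.index(markers[st])
        for j, p in enumerate(pos):
            c = float(c_t[j])
            plot_id = f"{transect}_p{p:02d}"
            richness = int(rng.poisson(config.mean_richness * (1 - 0.55 * c / 100.0)))
            richness = int(np.clip(richness, 2, len(cand_idx[st])))
            s_eff = config.regime_strength * (0.15 + 0.85 * c / 100.0)
            chosen = _select_species(
                config.assembly_regime, s_eff, cand_idx[st], richness, D, rng,
                prior=cand_prior[st],
            )
            if j <= 2 and marker_idx not in chosen:
                chosen[rng.integers(len(chosen))] = marker_idx
            weights = rng.dirichlet(np.ones(len(chosen)))
            if j <= 2 and marker_idx in chosen:
                weights[chosen.index(marker_idx)] *= 3.0
            weights /= weights.sum()
            total = max(10.0, 100.0 - c)
            covers = total * weights * np.exp(config.noise_sd * rng.normal(size=len(chosen)))
            covers = np.clip(covers, 0.1, 100.0)
            row = np.zeros(len(species_cols))
            row[0] = c
            for i_sp, cv in zip(chosen, covers):
                row[1 + i_sp] = cv
            rows.append(row)
            plot_ids.append(plot_id)
            meta_rows.append({"transect_id": transect, "site_type": st, "position_index": int(p)})
            focal_curve[plot_id] = c
            strength_eff_per_plot[plot_id] = s_eff

    cover_df = pd.DataFrame(rows, index=plot_ids, columns=species_cols)
    meta_df = pd.DataFrame(meta_rows, index=plot_ids)
    cover = CoverMatrix(cover_df, meta_df)
    truth = {
        "regime": config.assembly_regime,
        "regime_strength": config.regime_strength,
        "focal_curve": focal_curve,
        "strength_eff": strength_eff_per_plot,
        "species_assignment": assignment,
        "markers": markers,
        "seed": config.seed,
    }
    return SyntheticDataset(cover, traits, truth)


def inject_gradient_effect(
    dataset: SyntheticDataset,
    beta_linear: float,
    beta_quadratic: float,
    trait_set: TraitSet | None = None,
    n_null: int = 199,
    max_tries: int = 80,
    tol: float = 0.4,
    seed: int | None = None,
) -> SyntheticDataset:
    """Re-weight assemblages so plug-in SES tracks a target cover curve.

    The target is beta_linear * c + beta_quadratic * c^2 on the
    standardized cover axis (the axis the gradient models report on).
    For each plot with a non-zero target, candidate assemblages are
    redrawn at the plot's richness until the plug-in SES (Jost-corrected
    Rao against an internal ``n_null``-shuffle null) lands within ``tol``
    of the target; the closest candidate is kept otherwise.  Plots whose
    target is zero keep their original random assemblage, so a null
    injection is the identity.  Targets beyond the pool's achievable SES
    range raise with the observed achievable bounds.
    """
    if dataset.truth.get("regime") != "random":
        raise ValidationError("gradient injection requires a regime='random' dataset")
    if trait_set is None:
        trait_set = TraitSet("H", ("H",))
    rng = np.random.default_rng(dataset.truth["seed"] + 1 if seed is None else seed)

    focal_id = [c for c in dataset.cover.species_ids if c not in dataset.truth["species_assignment"]][0]
    pool = [s for s in dataset.cover.species_ids if s != focal_id]
    traits_pool = dataset.traits.subset_species(pool)
    D = gower_dissimilarity(traits_pool, trait_set).values
    S = len(pool)
    perms = np.stack([rng.permutation(S) for _ in range(n_null)])
    D_stack = np.stack([D[np.ix_(p, p)] for p in perms])

    def plug_in_ses(p_vec: np.ndarray) -> float:
        obs = 1.0 / (1.0 - p_vec @ D @ p_vec)
        sims = 1.0 / (1.0 - np.einsum("s,kst,t->k", p_vec, D_stack, p_vec))
        sd = sims.std(ddof=1)
        if sd <= 1e-12:
            return 0.0
        return float((obs - sims.mean()) / sd)

    cover_df = dataset.cover.cover.copy()
    meta = dataset.cover.plot_meta
    c_raw = cover_df[focal_id].to_numpy(dtype=float)
    c_s = (c_raw - c_raw.mean()) / c_raw.std(ddof=1)
    targets = beta_linear * c_s + beta_quadratic * c_s**2

    assignment = dataset.truth["species_assignment"]
    markers = dataset.truth["markers"]
    sp_pos = {s: i for i, s in enumerate(pool)}
    injected = {}
    for r, plot_id in enumerate(cover_df.index):
        target = float(targets[r])
        if abs(target) < 1e-12:
            continue
        st = meta.loc[plot_id, "site_type"]
        posj = int(meta.loc[plot_id, "position_index"])
        cand = np.array(
            [sp_pos[s] for s in pool if assignment[s] in ("shared", "unique_" + st)]
        )
        orig = cover_df.loc[plot_id, pool].to_numpy(dtype=float)
        richness = max(2, int((orig > 0).sum()))
        total = orig.sum() if orig.sum() > 0 else 10.0
        marker_idx = sp_pos[markers[st]]
        best = None
        seen = []
        for _ in range(max_tries):
            chosen = list(rng.choice(cand, size=min(richness, len(cand)), replace=False))
            if posj <= 2 and marker_idx not in chosen:
                chosen[rng.integers(len(chosen))] = marker_idx
            weights = rng.dirichlet(np.ones(len(chosen)))
            p_vec = np.zeros(S)
            p_vec[chosen] = weights
            ses = plug_in_ses(p_vec)
            seen.append(ses)
            dev = abs(ses - target)
            if best is None or dev < best[0]:
                best = (dev, chosen, weights, ses)
            if dev <= tol:
                break
        if best[0] > 3.0:
            raise ValidationError(
                f"target SES {target:.2f} for plot {plot_id!r} unattainable; "
                f"achievable range about [{min(seen):.2f}, {max(seen):.2f}]"
            )
        _, chosen, weights, realized = best
        new = np.zeros(S)
        new[chosen] = np.clip(total * weights, 0.1, 100.0)
        cover_df.loc[plot_id, pool] = new
        injected[plot_id] = {"target": target, "realized": realized}

    truth = dict(dataset.truth)
    truth.update(
        {
            "regime": "injected",
            "beta_linear": beta_linear,
            "beta_quadratic": beta_quadratic,
            "injection_trait_set": trait_set.name,
            "injected": injected,
        }
    )
    return SyntheticDataset(CoverMatrix(cover_df, meta.copy()), dataset.traits, truth)
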