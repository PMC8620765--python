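"""Tabular input/output and the shared data model.

Two containers flow through every stage of the analysis:

* :class:`CoverMatrix` — plots x species percent cover (visual estimates,
  0-100 per species; row sums may exceed 100 because vegetation layers
  overlap) plus per-plot metadata (transect, site type, position along
  the transect).
* :class:`TraitTable` — species x trait values with a per-trait metadata
  sidecar declaring the measurement kind (continuous / ordinal /
  categorical), units, an optional log10 transform, and the level set for
  non-continuous traits.

All files are UTF-8 CSV with "." decimal; the trait sidecar is YAML.
Validation happens at construction time so downstream stages can assume
well-formed inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fdgradient")

#: the seven traits used throughout: plant height, leaf dry matter content,
#: leaf area, seed mass, lateral spread, persistence of clonal growth organ,
#: number of clonal offspring.
CANONICAL_TRAITS: tuple[str, ...] = ("H", "LDMC", "LA", "SM", "LS", "PCGO", "NCO")

#: leaf-height-seed strategy triplet
LHS_TRAITS: tuple[str, ...] = ("LDMC", "H", "SM")

META_COLUMNS: tuple[str, ...] = ("transect_id", "site_type", "position_index")


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one trait column."""

    kind: str  # continuous | ordinal | categorical
    units: str = ""
    transform: str = "none"  # none | log10
    levels: tuple[str, ...] | None = None  # ordered for ordinal

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal", "categorical"):
            raise ValidationError(f"unknown trait kind {self.kind!r}")
        if self.transform not in ("none", "log10"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.kind in ("ordinal", "categorical") and not self.levels:
            raise ValidationError(f"{self.kind} trait needs a declared level set")


@dataclass(frozen=True)
class TraitSet:
    """A named, non-empty subset of trait ids."""

    name: str
    trait_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.trait_ids:
            raise ValidationError(f"trait set {self.name!r} is empty")


def canonical_trait_sets() -> list[TraitSet]:
    """The nine trait sets of the full analysis.

    Seven singletons, the LHS triplet (LDMC, H, SM) and "Multiple"
    (all seven traits pooled).
    """
    sets = [TraitSet(t, (t,)) for t in CANONICAL_TRAITS]
    sets.append(TraitSet("LHS", LHS_TRAITS))
    sets.append(TraitSet("Multiple", CANONICAL_TRAITS))
    return sets


@dataclass
class CoverMatrix:
    """Plots x species percent cover with per-plot metadata.

    ``cover`` is a DataFrame indexed by plot id with one float column per
    species; ``plot_meta`` is indexed identically with columns
    ``transect_id``, ``site_type`` and ``position_index``.
    """

    cover: pd.DataFrame
    plot_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- basic views ---------------------------------------------------
    @property
    def plot_ids(self) -> list[str]:
        return list(self.cover.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.cover.columns)

    @property
    def site_types(self) -> list[str]:
        return sorted(self.plot_meta["site_type"].unique())

    def validate(self) -> None:
        cov = self.cover
        if cov.index.has_duplicates:
            dups = cov.index[cov.index.duplicated()].tolist()
            raise ValidationError(f"duplicate plot ids: {dups}")
        if cov.columns.has_duplicates:
            dups = cov.columns[cov.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate species ids: {dups}")
        vals = cov.to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite cover at plot {cov.index[r]!r}, species {cov.columns[c]!r}"
            )
        neg = vals < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative cover {vals[r, c]} at plot {cov.index[r]!r}, "
                f"species {cov.columns[c]!r}"
            )
        over = vals > 100
        if over.any():
            r, c = np.argwhere(over)[0]
            raise ValidationError(
                f"cover {vals[r, c]} > 100 at plot {cov.index[r]!r}, "
                f"species {cov.columns[c]!r}"
            )
        meta = self.plot_meta
        missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise ValidationError(f"plot metadata missing columns: {missing_cols}")
        if not meta.index.equals(cov.index):
            raise ValidationError("plot metadata index does not match cover plots")
        if meta[list(META_COLUMNS)].isna().any().any():
            bad_plots = meta.index[meta[list(META_COLUMNS)].isna().any(axis=1)]
            raise ValidationError(f"incomplete metadata for plots: {list(bad_plots)}")
        pos = meta["position_index"]
        if (pos.astype(float) < 0).any() or (pos.astype(float) % 1 != 0).any():
            raise ValidationError("position_index must be an integer >= 0")

    def focal_cover(self, focal_species_id: str) -> pd.Series:
        """Percent cover of the focal species per plot."""
        if focal_species_id not in self.cover.columns:
            raise ValidationError(f"unknown focal species {focal_species_id!r}")
        return self.cover[focal_species_id]


@dataclass
class TraitTable:
    """Species x trait values with a trait-metadata sidecar.

    ``values`` is a DataFrame indexed by species id; continuous traits are
    float columns, ordinal/categorical traits hold level labels (object
    dtype). Missing cells are NaN and are never imputed here.
    """

    values: pd.DataFrame
    trait_meta: dict[str, TraitMeta]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate species ids: {dups}")
        for trait in df.columns:
            if trait not in self.trait_meta:
                raise ValidationError(f"trait {trait!r} absent from trait metadata")
            meta = self.trait_meta[trait]
            col = df[trait]
            obs = col[col.notna()]
            if meta.kind == "continuous":
                arr = pd.to_numeric(obs, errors="coerce")
                if arr.isna().any():
                    sp = obs.index[arr.isna()][0]
                    raise ValidationError(
                        f"non-numeric value {obs[sp]!r} for continuous trait "
                        f"{trait!r}, species {sp!r}"
                    )
                if not np.isfinite(arr.to_numpy(dtype=float)).all():
                    sp = obs.index[~np.isfinite(arr.to_numpy(dtype=float))][0]
                    raise ValidationError(
                        f"non-finite value for trait {trait!r}, species {sp!r}"
                    )
                if meta.transform == "log10" and (arr <= 0).any():
                    sp = obs.index[(arr <= 0)][0]
                    raise ValidationError(
                        f"log10 transform declared for trait {trait!r} but species "
                        f"{sp!r} has non-positive value {arr[sp]}"
                    )
            else:
                levels = set(meta.levels or ())
                bad = [v for v in obs.astype(str) if v not in levels]
                if bad:
                    sp = obs.index[obs.astype(str).map(lambda v: v not in levels)][0]
                    raise ValidationError(
                        f"value {bad[0]!r} of trait {trait!r} (species {sp!r}) "
                        f"not in declared levels {sorted(levels)}"
                    )

    def subset_species(self, species: Sequence[str]) -> "TraitTable":
        return TraitTable(self.values.loc[list(species)].copy(), dict(self.trait_meta))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cover_table(path: str | Path, layout: str = "wide") -> CoverMatrix:
    """Read a plot x species cover table.

    ``layout="wide"``: one row per plot with the metadata columns
    (plot_id, transect_id, site_type, position_index) followed by one
    column per species. ``layout="long"``: rows (plot_id, transect_id,
    site_type, position_index, species_id, cover); duplicate
    (plot, species) pairs are an error.
    """
    df = pd.read_csv(path)
    if layout == "wide":
        missing = [c for c in ("plot_id", *META_COLUMNS) if c not in df.columns]
        if missing:
            raise ValidationError(f"wide cover file missing columns {missing}")
        df = df.set_index("plot_id")
        df.index.name = None
        meta = df[list(META_COLUMNS)].copy()
        cover = df.drop(columns=list(META_COLUMNS)).astype(float)
    elif layout == "long":
        required = ("plot_id", *META_COLUMNS, "species_id", "cover")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"long cover file missing columns {missing}")
        dup = df.duplicated(subset=["plot_id", "species_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate (plot, species) pair ({row['plot_id']!r}, "
                f"{row['species_id']!r}) in long cover file"
            )
        cover = (
            df.pivot(index="plot_id", columns="species_id", values="cover")
            .fillna(0.0)
            .astype(float)
        )
        cover.columns.name = None
        cover.index.name = None
        meta = (
            df.drop_duplicates("plot_id")
            .set_index("plot_id")[list(META_COLUMNS)]
            .loc[cover.index]
        )
        meta.index.name = None
    else:
        raise ValidationError(f"unknown cover layout {layout!r}")
    meta["position_index"] = meta["position_index"].astype(int)
    return CoverMatrix(cover, meta)


def write_cover_table(cm: CoverMatrix, path: str | Path) -> Path:
    """Write a CoverMatrix in wide layout."""
    out = pd.concat([cm.plot_meta, cm.cover], axis=1)
    out.index.name = "plot_id"
    path = Path(path)
    out.to_csv(path, float_format="%.10g")
    return path


def read_trait_table(path: str | Path, meta_path: str | Path) -> TraitTable:
    """Read a species x trait CSV plus its YAML metadata sidecar."""
    with open(meta_path, "r", encoding="utf-8") as fh:
        raw_meta = yaml.safe_load(fh)
    trait_meta = {
        t: TraitMeta(
            kind=m["kind"],
            units=m.get("units", ""),
            transform=m.get("transform", "none"),
            levels=tuple(str(x) for x in m["levels"]) if m.get("levels") else None,
        )
        for t, m in raw_meta.items()
    }
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    for trait in df.columns:
        if trait not in trait_meta:
            raise ValidationError(f"trait {trait!r} absent from metadata sidecar")
        if trait_meta[trait].kind == "continuous":
            df[trait] = pd.to_numeric(df[trait], errors="raise")
        else:
            df[trait] = df[trait].map(lambda v: v if pd.isna(v) else str(v))
    return TraitTable(df, trait_meta)


def write_trait_table(tt: TraitTable, path: str | Path, meta_path: str | Path) -> tuple[Path, Path]:
    path, meta_path = Path(path), Path(meta_path)
    out = tt.values.copy()
    out.index.name = "species_id"
    out.to_csv(path, float_format="%.10g")
    raw = {}
    for t, m in tt.trait_meta.items():
        entry: dict = {"kind": m.kind, "units": m.units, "transform": m.transform}
        if m.levels is not None:
            entry["levels"] = list(m.levels)
        raw[t] = entry
    with open(meta_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
    return path, meta_path


def align_cover_traits(
    cover: CoverMatrix, traits: TraitTable, focal_species_id: str | None = None
) -> tuple[CoverMatrix, TraitTable]:
    """Match species between cover and trait tables.

    Species present in the cover matrix but lacking *all* trait values (or
    absent from the trait table entirely) are dropped with a logged
    warning; the focal species is exempt because it never enters trait
    computations. Name resolution is out of scope: ids must match exactly.
    """
    keep: list[str] = []
    dropped: list[str] = []
    for sp in cover.species_ids:
        if focal_species_id is not None and sp == focal_species_id:
            keep.append(sp)
            continue
        if sp not in traits.values.index or traits.values.loc[sp].isna().all():
            dropped.append(sp)
        else:
            keep.append(sp)
    if dropped:
        logger.warning(
            "dropping %d species without any trait values: %s", len(dropped), dropped
        )
    cm = CoverMatrix(cover.cover[keep].copy(), cover.plot_meta.copy())
    trait_species = [s for s in keep if s in traits.values.index]
    return cm, traits.subset_species(trait_species)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write stage-output tables plus a run manifest.

    Each table lands in ``out_dir/<name>.csv``; ``manifest.yaml`` records
    the configuration, the seed and the package version.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.12g")
        paths[name] = p
    manifest = {
        "package": "fdgradient",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config) if config is not None else None,
        "tables": {k: str(v.name) for k, v in paths.items()},
    }
    mpath = out_dir / "manifest.yaml"
    with open(mpath, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    paths["manifest"] = mpath
    return paths


def _jsonable(obj):
    """Recursively convert dataclasses / numpy scalars for YAML output."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
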