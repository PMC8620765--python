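"""End-to-end orchestration: simulate/read -> FD -> SES -> models + composition.

A single top-level seed deterministically derives every stage seed, so a
run is a pure function of (inputs, config, seed).  Each stage's output
is written to the output directory together with a manifest recording
the configuration, the seed, per-stage content hashes and wall times;
reruns with ``resume=True`` reload stages whose recorded input hash is
unchanged instead of recomputing them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composition import anosim, nmds
from .dissimilarity import bray_curtis
from .fdiversity import fd_per_plot
from .gradient_models import run_all_models
from .io_data import (
    CoverMatrix,
    TraitTable,
    ValidationError,
    canonical_trait_sets,
    read_cover_table,
    read_trait_table,
    write_cover_table,
    write_results,
    write_trait_table,
)
from .null_models import NullConfig, ses_for_plots
from .synthetic_data import SimConfig, generate

logger = logging.getLogger("fdgradient")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``sim`` (a :class:`SimConfig`) or the three input paths must
    be set.  ``seed`` is the single top-level seed; stage seeds are
    derived from it.
    """

    out_dir: str = "fdgradient_out"
    seed: int = 0
    sim: SimConfig | None = None
    cover_path: str | None = None
    trait_path: str | None = None
    trait_meta_path: str | None = None
    cover_layout: str = "wide"
    focal_species_id: str = "focal_dominant"
    trait_sets: list[str] | None = None  # None -> the 9 canonical sets
    n_permutations: int = 999
    shuffle_scheme: str = "auto"
    null_pool: str = "regional"
    standardize: str = "jost"
    random_structure: str = "intercept_slope"
    anosim_permutations: int = 999
    nmds_k: int = 2
    nmds_starts: int = 4
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def derive_seeds(seed: int) -> dict[str, int]:
    """Derive stage seeds (< 2^31) from the top-level seed."""
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "null", "anosim", "nmds")
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)
    }


def _hash_frames(*frames) -> str:
    h = hashlib.sha256()
    for f in frames:
        if isinstance(f, pd.DataFrame):
            h.update(f.to_csv().encode())
        else:
            h.update(repr(f).encode())
    return h.hexdigest()


def _select_trait_sets(names: list[str] | None):
    sets = canonical_trait_sets()
    if names is None:
        return sets
    by_name = {s.name: s for s in sets}
    unknown = [n for n in names if n not in by_name]
    if unknown:
        raise ValidationError(f"unknown trait sets {unknown}")
    return [by_name[n] for n in names]


def run_pipeline(config: RunConfig, resume: bool = False) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of all outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    seeds = derive_seeds(config.seed)
    stage_info: dict[str, dict] = {}
    prev_manifest = {}
    mpath = out_dir / "manifest.yaml"
    if resume and mpath.exists():
        with open(mpath, "r", encoding="utf-8") as fh:
            prev_manifest = yaml.safe_load(fh) or {}

    def stage(name):
        def deco(fn):
            def run(*args, **kwargs):
                t0 = time.perf_counter()
                try:
                    out = fn(*args, **kwargs)
                except Exception as exc:
                    failed_marker.write_text(f"stage {name}: {exc}\n")
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                stage_info.setdefault(name, {})["seconds"] = round(
                    time.perf_counter() - t0, 3
                )
                logger.info("stage %s done in %.2fs", name, stage_info[name]["seconds"])
                return out
            return run
        return deco

    @stage("input")
    def _input():
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=seeds["simulate"])
            ds = generate(sim)
            write_cover_table(ds.cover, out_dir / "cover.csv")
            write_trait_table(ds.traits, out_dir / "traits.csv", out_dir / "trait_meta.yaml")
            with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(ds.truth, fh, indent=1, default=str)
            return ds.cover, ds.traits, config.sim.focal_species_id
        if not (config.cover_path and config.trait_path and config.trait_meta_path):
            raise ValidationError("either sim or all three input paths must be set")
        cover = read_cover_table(config.cover_path, layout=config.cover_layout)
        traits = read_trait_table(config.trait_path, config.trait_meta_path)
        return cover, traits, config.focal_species_id

    cover, traits, focal = _input()
    trait_sets = _select_trait_sets(config.trait_sets)
    input_hash = _hash_frames(cover.cover, cover.plot_meta, traits.values, config)

    def cached(name, compute, reader, path):
        recorded = (prev_manifest.get("stages") or {}).get(name, {})
        if resume and recorded.get("input_hash") == input_hash and path.exists():
            logger.info("stage %s: reusing cached output", name)
            stage_info[name] = {"cached": True, **recorded}
            return reader(path)
        result = compute()
        stage_info.setdefault(name, {})["input_hash"] = input_hash
        return result

    @stage("fd")
    def _fd():
        return fd_per_plot(cover, traits, focal, trait_sets)

    fd_table = cached("fd", _fd, lambda p: pd.read_csv(p), out_dir / "fd.csv")

    @stage("ses")
    def _ses():
        nc = NullConfig(
            n_permutations=config.n_permutations,
            shuffle_scheme=config.shuffle_scheme,
            pool=config.null_pool,
            seed=seeds["null"],
            standardize=config.standardize,
        )
        return ses_for_plots(cover, traits, focal, trait_sets, nc)

    ses_table = cached("ses", _ses, lambda p: pd.read_csv(p), out_dir / "ses.csv")

    @stage("models")
    def _models():
        # None lets run_all_models apply the canonical report row order
        names = None if config.trait_sets is None else [ts.name for ts in trait_sets]
        return run_all_models(
            ses_table,
            cover.focal_cover(focal),
            cover.plot_meta,
            names,
            config.random_structure,
        )

    fits, model_table = _models()

    @stage("composition")
    def _composition():
        D = bray_curtis(cover)
        groups = cover.plot_meta["site_type"].loc[list(D.ids)]
        ano = anosim(
            D,
            groups,
            n_permutations=config.anosim_permutations,
            rng=np.random.default_rng(seeds["anosim"]),
        )
        ords = nmds(
            D,
            k=config.nmds_k,
            n_starts=config.nmds_starts,
            rng=np.random.default_rng(seeds["nmds"]),
        )
        return ano, ords

    ano, ords = _composition()
    anosim_table = pd.DataFrame(
        [
            {
                "r_statistic": ano.r_statistic,
                "p_value": ano.p_value,
                "n_permutations": ano.n_permutations,
                **{f"n_{k}": v for k, v in ano.group_sizes.items()},
                "nmds_stress": ords.stress,
                "nmds_converged": ords.converged,
            }
        ]
    )

    tables = {
        "fd": fd_table,
        "ses": ses_table,
        "model_table": model_table,
        "anosim": anosim_table,
        "nmds_coords": ords.coordinates.reset_index(),
    }
    paths = write_results(tables, out_dir, config=config, seed=config.seed)

    if config.make_plots:
        paths["figures"] = _make_plots(out_dir, ses_table, cover, focal, ords)

    # extend the manifest with stage provenance
    with open(paths["manifest"], "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    manifest["stage_seeds"] = seeds
    manifest["stages"] = stage_info
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return paths


def _make_plots(out_dir: Path, ses_table, cover, focal, ords) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    c = cover.focal_cover(focal)
    sets = list(ses_table["trait_set"].unique())
    ncol = 3
    nrow = int(np.ceil(len(sets) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, ts in zip(axes.ravel(), sets):
        sub = ses_table[ses_table["trait_set"] == ts]
        x = c.reindex(sub["plot_id"]).to_numpy(dtype=float)
        y = sub["ses"].to_numpy(dtype=float)
        ok = np.isfinite(y)
        ax.scatter(x[ok], y[ok], s=8, alpha=0.6)
        if ok.sum() > 3:
            coef = np.polyfit(x[ok], y[ok], 2)
            xs = np.linspace(x[ok].min(), x[ok].max(), 100)
            ax.plot(xs, np.polyval(coef, xs), "k-")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(ts)
        ax.set_xlabel("focal cover (%)")
        ax.set_ylabel("SES")
    for ax in axes.ravel()[len(sets):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(fig_dir / "ses_vs_cover.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    coords = ords.coordinates
    groups = cover.plot_meta["site_type"].reindex(coords.index)
    for g, marker in zip(sorted(groups.unique()), "o^sv"):
        sel = groups == g
        ax.scatter(
            coords.loc[sel, coords.columns[0]],
            coords.loc[sel, coords.columns[1]] if coords.shape[1] > 1 else 0 * sel,
            label=str(g),
            marker=marker,
            alpha=0.7,
        )
    ax.legend()
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1] if coords.shape[1] > 1 else "")
    fig.tight_layout()
    fig.savefig(fig_dir / "nmds.png", dpi=120)
    plt.close(fig)
    return fig_dir
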