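import itertools

import numpy as np
import pandas as pd
import pytest

from fdgradient import (
    NullConfig,
    TraitMeta,
    TraitSet,
    TraitTable,
    fd_per_plot,
    gower_dissimilarity,
    ses_for_plots,
    shuffle_traits,
)

from conftest import make_cover


@pytest.fixture
def mixed_traits():
    return TraitTable(
        pd.DataFrame(
            {"H": [0.1, 0.5, 0.9, 0.3], "PCGO": ["<1yr", "1-2yr", ">2yr", "<1yr"]},
            index=["s1", "s2", "s3", "s4"],
        ),
        {
            "H": TraitMeta("continuous", "m"),
            "PCGO": TraitMeta("ordinal", levels=("<1yr", "1-2yr", ">2yr")),
        },
    )


@pytest.mark.parametrize("scheme", ["rows_joint", "per_column"])
def test_shuffle_preserves_each_traits_multiset(mixed_traits, scheme):
    out = shuffle_traits(mixed_traits, scheme, np.random.default_rng(4))
    for col in mixed_traits.trait_ids:
        assert sorted(map(str, out.values[col])) == sorted(map(str, mixed_traits.values[col]))
    assert list(out.values.index) == list(mixed_traits.values.index)


def test_rows_joint_moves_whole_rows(mixed_traits):
    out = shuffle_traits(mixed_traits, "rows_joint", np.random.default_rng(4))
    original_rows = {tuple(map(str, r)) for r in mixed_traits.values.to_numpy()}
    shuffled_rows = {tuple(map(str, r)) for r in out.values.to_numpy()}
    assert original_rows == shuffled_rows  # inter-trait correlation preserved


def test_single_species_shuffle_is_identity():
    tt = TraitTable(
        pd.DataFrame({"H": [0.4]}, index=["only"]), {"H": TraitMeta("continuous")}
    )
    out = shuffle_traits(tt, "rows_joint", np.random.default_rng(0))
    pd.testing.assert_frame_equal(out.values, tt.values)


def test_fixed_seed_reproducible(mixed_traits):
    a = shuffle_traits(mixed_traits, "per_column", np.random.default_rng(9))
    b = shuffle_traits(mixed_traits, "per_column", np.random.default_rng(9))
    pd.testing.assert_frame_equal(a.values, b.values)


def _small_system():
    cover = make_cover(
        {
            "p1": {"foc": 50.0, "s1": 30.0, "s2": 10.0, "s3": 10.0},
            "p2": {"foc": 20.0, "s1": 10.0, "s2": 40.0, "s3": 30.0},
        }
    )
    traits = TraitTable(
        pd.DataFrame({"H": [0.1, 0.5, 0.9]}, index=["s1", "s2", "s3"]),
        {"H": TraitMeta("continuous", "m")},
    )
    return cover, traits


def test_exhaustive_enumeration_matches_explicit_oracle():
    """3-species pool: SES over all 3! = 6 permutations equals a hand-rolled
    enumeration of shuffled Rao values."""
    cover, traits = _small_system()
    ts = TraitSet("H", ("H",))
    perms = [np.array(p) for p in itertools.permutations(range(3))]
    res = ses_for_plots(cover, traits, "foc", [ts], permutations=perms)
    D = gower_dissimilarity(traits, ts).values
    plot_p = {
        "p1": np.array([30.0, 10.0, 10.0]) / 50.0,
        "p2": np.array([10.0, 40.0, 30.0]) / 80.0,
    }
    for plot, p in plot_p.items():
        obs = 1 / (1 - p @ D @ p)
        sims = np.array([1 / (1 - p @ D[np.ix_(q, q)] @ p) for q in perms])
        expected = (obs - sims.mean()) / sims.std(ddof=1)
        got = res[res["plot_id"] == plot]["ses"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)


def test_observed_index_agrees_with_fd_per_plot():
    cover, traits = _small_system()
    ts = TraitSet("H", ("H",))
    res = ses_for_plots(cover, traits, "foc", [ts], config=NullConfig(n_permutations=5, seed=0))
    fd = fd_per_plot(cover, traits, "foc", [ts]).set_index("plot_id")
    for _, row in res.iterrows():
        assert row["i_obs"] == pytest.approx(fd.loc[row["plot_id"], "q_jost"], abs=1e-12)


def test_scheme_choice_is_distributionally_irrelevant_for_single_trait():
    """With one trait, joint row shuffles and column shuffles induce the
    same null distribution; exhaustive enumeration is the reference."""
    cover, traits = _small_system()
    ts = TraitSet("H", ("H",))
    perms = [np.array(p) for p in itertools.permutations(range(3))]
    exact = ses_for_plots(cover, traits, "foc", [ts], permutations=perms)
    for scheme in ("rows_joint", "per_column"):
        sampled = ses_for_plots(
            cover, traits, "foc", [ts],
            config=NullConfig(n_permutations=3000, shuffle_scheme=scheme, seed=1),
        )
        merged = exact.merge(sampled, on="plot_id", suffixes=("_ex", "_mc"))
        # Monte-Carlo noise in the 3000-draw null mean/sd dominates the gap
        assert np.allclose(merged["ses_ex"], merged["ses_mc"], atol=0.15)


def test_identical_trait_values_flag_degenerate():
    cover = make_cover({"p1": {"foc": 10.0, "s1": 40.0, "s2": 40.0}})
    traits = TraitTable(
        pd.DataFrame({"H": [1.0, 1.0]}, index=["s1", "s2"]),
        {"H": TraitMeta("continuous")},
    )
    res = ses_for_plots(
        cover, traits, "foc", [TraitSet("H", ("H",))],
        config=NullConfig(n_permutations=20, seed=0),
    )
    assert res["degenerate"].all()
    assert res["ses"].isna().all()


def test_composition_matrix_untouched(default_dataset):
    before = default_dataset.cover.cover.copy()
    ses_for_plots(
        default_dataset.cover,
        default_dataset.traits,
        "focal_dominant",
        [TraitSet("H", ("H",))],
        config=NullConfig(n_permutations=19, seed=3),
    )
    pd.testing.assert_frame_equal(default_dataset.cover.cover, before)


def test_invariant_to_order_preserving_relabeling():
    cover, traits = _small_system()
    ts = TraitSet("H", ("H",))
    cfg = NullConfig(n_permutations=200, seed=7)
    base = ses_for_plots(cover, traits, "foc", [ts], config=cfg)

    ren_cover = make_cover(
        {
            "plotX": {"dom": 50.0, "a1": 30.0, "a2": 10.0, "a3": 10.0},
            "plotY": {"dom": 20.0, "a1": 10.0, "a2": 40.0, "a3": 30.0},
        }
    )
    ren_traits = TraitTable(
        pd.DataFrame({"H": [0.1, 0.5, 0.9]}, index=["a1", "a2", "a3"]),
        {"H": TraitMeta("continuous", "m")},
    )
    renamed = ses_for_plots(ren_cover, ren_traits, "dom", [ts], config=cfg)
    np.testing.assert_allclose(base["ses"], renamed["ses"], atol=1e-12)


def test_plots_below_two_species_are_excluded():
    cover = make_cover(
        {
            "p1": {"foc": 90.0, "s1": 10.0, "s2": 0.0, "s3": 0.0},
            "p2": {"foc": 20.0, "s1": 10.0, "s2": 40.0, "s3": 30.0},
        }
    )
    _, traits = _small_system()
    res = ses_for_plots(
        cover, traits, "foc", [TraitSet("H", ("H",))],
        config=NullConfig(n_permutations=9, seed=0),
    )
    assert list(res["plot_id"]) == ["p2"]


def test_per_transect_pool_runs_and_differs_from_regional():
    cover, traits = _small_system()
    ts = TraitSet("H", ("H",))
    reg = ses_for_plots(cover, traits, "foc", [ts], config=NullConfig(99, seed=5))
    per = ses_for_plots(
        cover, traits, "foc", [ts], config=NullConfig(99, pool="per_transect", seed=5)
    )
    assert len(reg) == len(per)  # same plots standardized in both pools
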