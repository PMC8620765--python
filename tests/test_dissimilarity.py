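import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdgradient import (
    TraitMeta,
    TraitSet,
    TraitTable,
    ValidationError,
    bray_curtis,
    gower_dissimilarity,
)

from conftest import make_cover


def _traits(df, meta):
    return TraitTable(df, meta)


def test_identical_trait_profiles_have_zero_distance():
    tt = _traits(
        pd.DataFrame({"H": [1.0, 1.0, 2.0], "LDMC": [5.0, 5.0, 7.0]},
                     index=["a", "b", "c"]),
        {"H": TraitMeta("continuous"), "LDMC": TraitMeta("continuous")},
    )
    D = gower_dissimilarity(tt, TraitSet("both", ("H", "LDMC")))
    assert D.values[0, 1] == pytest.approx(0.0, abs=1e-15)


def test_range_normalization_pool_extremes_reach_one():
    tt = _traits(
        pd.DataFrame({"H": [0.2, 1.0, 5.0]}, index=["lo", "mid", "hi"]),
        {"H": TraitMeta("continuous")},
    )
    D = gower_dissimilarity(tt, TraitSet("H", ("H",)))
    assert D.values[0, 2] == pytest.approx(1.0)
    assert 0 < D.values[0, 1] < 1


def test_gower_matches_hand_computed_per_trait_average():
    """4 species x (1 continuous + 1 ordinal with ties): independent oracle.

    The expected matrix is recomputed here pair by pair: continuous part
    |x_i-x_j|/range, ordinal part via tie-corrected ranks, then the mean
    of the two parts.
    """
    cont = {"a": 0.0, "b": 2.0, "c": 6.0, "d": 10.0}
    levels = ("low", "mid", "high")
    ordv = {"a": "low", "b": "low", "c": "mid", "d": "high"}
    tt = _traits(
        pd.DataFrame({"X": cont, "O": ordv}),
        {"X": TraitMeta("continuous"), "O": TraitMeta("ordinal", levels=levels)},
    )
    # oracle: ranks of (low, low, mid, high) = (1.5, 1.5, 3, 4); ties (2,2,1,1)
    ranks = {"a": 1.5, "b": 1.5, "c": 3.0, "d": 4.0}
    ties = {"a": 2.0, "b": 2.0, "c": 1.0, "d": 1.0}
    denom = 4.0 - 1.5 - (1 - 1) / 2 - (2 - 1) / 2  # r_max - r_min - tie terms
    species = list(cont)
    expected = np.zeros((4, 4))
    for i, si in enumerate(species):
        for j, sj in enumerate(species):
            if i == j:
                continue
            dx = abs(cont[si] - cont[sj]) / 10.0
            if ordv[si] == ordv[sj]:
                do = 0.0
            else:
                do = (
                    abs(ranks[si] - ranks[sj])
                    - (ties[si] - 1) / 2
                    - (ties[sj] - 1) / 2
                ) / denom
            expected[i, j] = (dx + do) / 2
    D = gower_dissimilarity(tt, TraitSet("both", ("X", "O")))
    np.testing.assert_allclose(D.values, expected, atol=1e-12)


def test_gower_invariant_to_trait_order_and_affine_rescaling():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {"H": rng.uniform(0.1, 2, 8), "LDMC": rng.uniform(100, 400, 8)},
        index=[f"s{i}" for i in range(8)],
    )
    meta = {"H": TraitMeta("continuous"), "LDMC": TraitMeta("continuous")}
    base = gower_dissimilarity(_traits(df, meta), TraitSet("b", ("H", "LDMC")))
    swapped = gower_dissimilarity(_traits(df[["LDMC", "H"]], meta), TraitSet("b", ("LDMC", "H")))
    np.testing.assert_allclose(base.values, swapped.values, atol=1e-12)
    rescaled = df.copy()
    rescaled["H"] = 3.5 * rescaled["H"] - 12.0  # affine map, range-normalized away
    again = gower_dissimilarity(_traits(rescaled, meta), TraitSet("b", ("H", "LDMC")))
    np.testing.assert_allclose(base.values, again.values, atol=1e-10)


def test_zero_range_trait_contributes_zero():
    tt = _traits(
        pd.DataFrame({"H": [1.0, 1.0], "LDMC": [100.0, 300.0]}, index=["a", "b"]),
        {"H": TraitMeta("continuous"), "LDMC": TraitMeta("continuous")},
    )
    D = gower_dissimilarity(tt, TraitSet("b", ("H", "LDMC")))
    # mean over two traits: (0 + 1) / 2
    assert D.values[0, 1] == pytest.approx(0.5)


def test_pair_sharing_no_trait_is_error():
    tt = _traits(
        pd.DataFrame({"H": [1.0, np.nan], "SM": [np.nan, 2.0]}, index=["a", "b"]),
        {"H": TraitMeta("continuous"), "SM": TraitMeta("continuous")},
    )
    with pytest.raises(ValidationError, match="'a'.*'b'|'b'.*'a'"):
        gower_dissimilarity(tt, TraitSet("b", ("H", "SM")))


def test_missing_traits_use_pairwise_deletion():
    tt = _traits(
        pd.DataFrame(
            {"H": [0.0, 1.0, 0.5], "SM": [0.0, np.nan, 1.0]},
            index=["a", "b", "c"],
        ),
        {"H": TraitMeta("continuous"), "SM": TraitMeta("continuous")},
    )
    D = gower_dissimilarity(tt, TraitSet("b", ("H", "SM")))
    assert D.values[0, 1] == pytest.approx(1.0)  # only H observed in both
    assert D.values[1, 2] == pytest.approx(0.5)  # only H observed in both
    assert D.values[0, 2] == pytest.approx(0.75)  # mean of the two traits


def test_bray_curtis_forced_values():
    cm = make_cover(
        {
            "p1": {"a": 3.0, "b": 0.0, "c": 1.0},
            "p2": {"a": 1.0, "b": 2.0, "c": 1.0},
            "p3": {"a": 3.0, "b": 0.0, "c": 1.0},
            "p4": {"a": 0.0, "b": 5.0, "c": 0.0},
        }
    )
    D = bray_curtis(cm).to_frame()
    assert D.loc["p1", "p2"] == pytest.approx(0.5)  # (2+2+0)/(4+2+2)
    assert D.loc["p1", "p3"] == pytest.approx(0.0)  # identical plots
    # p1 uses {a, c}, p4 only b: complete turnover
    assert D.loc["p1", "p4"] == pytest.approx(1.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.lists(st.floats(0.1, 100), min_size=2, max_size=6),
    c=st.floats(0.05, 20),
)
def test_bray_curtis_scalar_multiple_closed_form(x, c):
    """BC(x, c*x) = |1 - c| / (1 + c) for any positive scalar c."""
    x = np.array(x)
    cm = make_cover(
        {
            "p1": {f"s{i}": min(v, 100.0) for i, v in enumerate(x)},
            "p2": {f"s{i}": min(v * c, 100.0) for i, v in enumerate(x)},
        }
    )
    # recompute c after clipping to stay within the percent bound
    a = cm.cover.loc["p1"].to_numpy()
    b = cm.cover.loc["p2"].to_numpy()
    expected = np.abs(a - b).sum() / (a + b).sum()
    D = bray_curtis(cm)
    assert D.values[0, 1] == pytest.approx(expected, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_symmetry_and_zero_diagonal(seed):
    rng = np.random.default_rng(seed)
    n_sp, n_plot = rng.integers(3, 8), rng.integers(2, 6)
    cm = make_cover(
        {
            f"p{i}": {f"s{j}": float(rng.uniform(0, 60)) for j in range(n_sp)}
            for i in range(n_plot)
        }
    )
    tt = _traits(
        pd.DataFrame(
            {"H": rng.uniform(0.1, 2, n_sp), "SM": rng.uniform(0.1, 9, n_sp)},
            index=[f"s{j}" for j in range(n_sp)],
        ),
        {"H": TraitMeta("continuous"), "SM": TraitMeta("continuous")},
    )
    for D in (bray_curtis(cm), gower_dissimilarity(tt, TraitSet("b", ("H", "SM")))):
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0)
        assert (D.values >= 0).all() and (D.values <= 1 + 1e-12).all()
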