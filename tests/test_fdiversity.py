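import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdgradient import (
    DissimilarityMatrix,
    PlotAbundance,
    TraitMeta,
    TraitSet,
    TraitTable,
    ValidationError,
    exclude_focal,
    fd_per_plot,
    gower_dissimilarity,
    jost_correct,
    rao_q,
)

from conftest import make_cover


def _dmat(ids, values):
    return DissimilarityMatrix(tuple(ids), np.array(values, dtype=float))


class TestExcludeFocal:
    def test_renormalizes_remaining_covers(self):
        cm = make_cover({"p1": {"foc": 80.0, "spA": 15.0, "spB": 5.0}})
        (pa,) = exclude_focal(cm, "foc")
        assert pa.species_ids == ("spA", "spB")
        np.testing.assert_allclose(pa.p, [0.75, 0.25])

    def test_monodominant_plot_is_flagged_empty(self):
        cm = make_cover({"p1": {"foc": 100.0, "spA": 0.0}})
        (pa,) = exclude_focal(cm, "foc")
        assert pa.empty and pa.n_species == 0

    def test_zero_focal_cover_leaves_proportions_unchanged(self):
        cm = make_cover({"p1": {"foc": 0.0, "spA": 30.0, "spB": 10.0}})
        (pa,) = exclude_focal(cm, "foc")
        np.testing.assert_allclose(pa.p, [0.75, 0.25])

    def test_unknown_focal_is_error(self):
        cm = make_cover({"p1": {"spA": 30.0}})
        with pytest.raises(ValidationError, match="nope"):
            exclude_focal(cm, "nope")


class TestRaoQ:
    def test_single_species_is_zero(self):
        pa = PlotAbundance("p", ("a",), np.array([1.0]))
        assert rao_q(pa, _dmat(["a"], [[0.0]])) == 0.0

    def test_two_maximally_distinct_equal_species(self):
        pa = PlotAbundance("p", ("a", "b"), np.array([0.5, 0.5]))
        D = _dmat(["a", "b"], [[0, 1], [1, 0]])
        assert rao_q(pa, D) == pytest.approx(0.5)

    def test_fixed_three_species_matches_double_sum(self):
        p = np.array([0.2, 0.3, 0.5])
        d = np.array([[0, 0.4, 0.9], [0.4, 0, 0.2], [0.9, 0.2, 0]])
        expected = sum(
            d[i, j] * p[i] * p[j] for i in range(3) for j in range(3)
        )
        pa = PlotAbundance("p", ("a", "b", "c"), p)
        assert rao_q(pa, _dmat(["a", "b", "c"], d)) == pytest.approx(expected, abs=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        s = int(rng.integers(2, 12))
        p = rng.dirichlet(np.ones(s))
        d = rng.uniform(0, 1, (s, s))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(s)]
        pa = PlotAbundance("p", tuple(ids), p)
        brute = sum(d[i, j] * p[i] * p[j] for i in range(s) for j in range(s))
        assert rao_q(pa, _dmat(ids, d)) == pytest.approx(brute, abs=1e-12)

    def test_species_order_permutation_invariant(self):
        rng = np.random.default_rng(2)
        s = 6
        p = rng.dirichlet(np.ones(s))
        d = rng.uniform(0, 1, (s, s))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(s)]
        q1 = rao_q(PlotAbundance("p", tuple(ids), p), _dmat(ids, d))
        perm = rng.permutation(s)
        q2 = rao_q(
            PlotAbundance("p", tuple(ids[i] for i in perm), p[perm]),
            _dmat(ids, d),
        )
        assert q1 == pytest.approx(q2, abs=1e-14)

    def test_unit_distance_reduces_to_simpson_complement(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(5))
        d = 1.0 - np.eye(5)
        ids = [f"s{i}" for i in range(5)]
        q = rao_q(PlotAbundance("p", tuple(ids), p), _dmat(ids, d))
        assert q == pytest.approx(1 - (p**2).sum(), abs=1e-14)

    def test_merging_functionally_identical_species_preserves_q(self):
        # species b and c share a trait row: merging them (summing p) leaves Q fixed
        d = np.array(
            [[0, 0.6, 0.6], [0.6, 0, 0.0], [0.6, 0.0, 0]]
        )
        p3 = np.array([0.5, 0.2, 0.3])
        q3 = rao_q(PlotAbundance("p", ("a", "b", "c"), p3), _dmat(["a", "b", "c"], d))
        d2 = np.array([[0, 0.6], [0.6, 0]])
        q2 = rao_q(PlotAbundance("p", ("a", "bc"), np.array([0.5, 0.5])), _dmat(["a", "bc"], d2))
        assert q3 == pytest.approx(q2, abs=1e-14)

    def test_species_missing_from_matrix_is_error(self):
        pa = PlotAbundance("p", ("a", "z"), np.array([0.5, 0.5]))
        with pytest.raises(ValidationError, match="z"):
            rao_q(pa, _dmat(["a", "b"], [[0, 1], [1, 0]]))


class TestJost:
    @pytest.mark.parametrize("q,expected", [(0.0, 1.0), (0.5, 2.0), (0.75, 4.0)])
    def test_equivalent_numbers(self, q, expected):
        assert jost_correct(q) == pytest.approx(expected)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 0.99, 50)
        vals = [jost_correct(q) for q in grid]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("bad", [1.0, 1.5, -0.1])
    def test_out_of_range_is_error(self, bad):
        with pytest.raises(ValidationError):
            jost_correct(bad)


class TestFdPerPlot:
    def test_design_scale_row_count(self, default_dataset):
        table = fd_per_plot(default_dataset.cover, default_dataset.traits, "focal_dominant")
        assert len(table) == 120 * 9
        assert (table["q_raw"] >= 0).all() and (table["q_raw"] < 1).all()
        np.testing.assert_allclose(table["q_jost"], 1 / (1 - table["q_raw"]))

    def test_identical_trait_values_give_zero_q(self):
        cm = make_cover({"p1": {"foc": 10.0, "a": 30.0, "b": 20.0, "c": 10.0}})
        tt = TraitTable(
            pd.DataFrame({"H": [1.0, 1.0, 1.0], "SM": [2.0, 5.0, 9.0]},
                         index=["a", "b", "c"]),
            {"H": TraitMeta("continuous"), "SM": TraitMeta("continuous")},
        )
        table = fd_per_plot(cm, tt, "foc", [TraitSet("H", ("H",))])
        assert table["q_raw"].iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_equals_manual_composition_of_stages(self, default_dataset):
        """fd_per_plot == exclude_focal -> gower -> rao_q composed by hand."""
        cover, traits = default_dataset.cover, default_dataset.traits
        ts = TraitSet("LHS", ("LDMC", "H", "SM"))
        table = fd_per_plot(cover, traits, "focal_dominant", [ts])
        pool = [s for s in traits.species_ids if s != "focal_dominant"]
        D = gower_dissimilarity(traits.subset_species(pool), ts)
        for pa in exclude_focal(cover, "focal_dominant")[:10]:
            q = rao_q(pa, D)
            row = table[table["plot_id"] == pa.plot_id].iloc[0]
            assert row["q_raw"] == pytest.approx(q, abs=1e-12)
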