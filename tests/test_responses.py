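"""Species-level response indices and their assembly nulls."""

import itertools

import numpy as np
import pandas as pd
import pytest

import phylotank as pt
from conftest import make_meta, make_table


def mc_se(z: float, n_null: int) -> float:
    """Delta-method standard error of a Monte-Carlo z estimate."""
    return np.sqrt((1 + z**2 / 2) / n_null)


class TestSizePreference:
    @pytest.fixture
    def four_plants(self):
        # log10 capacities 1, 2, 3, 4
        return make_meta([10.0, 100.0, 1000.0, 10000.0])

    def test_toy_closed_form(self, four_plants):
        """Two colonists both in the largest plant: the uniform-placement
        null has mean 2.5 and per-individual variance 1.25, so
        z = 1.5 / sqrt(0.625)."""
        tab = make_table([[0], [0], [0], [2]], ["s1"])
        res = pt.size_preference(tab, four_plants)
        assert res.loc[0, "observed"] == pytest.approx(4.0)
        assert res.loc[0, "null_mean"] == pytest.approx(2.5)
        assert res.loc[0, "z"] == pytest.approx(1.5 / np.sqrt(0.625))
        assert not res.loc[0, "significant"]

    def test_montecarlo_matches_closed_form(self, four_plants, rng):
        tab = make_table([[0], [0], [0], [2]], ["s1"])
        exact = pt.size_preference(tab, four_plants).loc[0, "z"]
        mc = pt.size_preference(tab, four_plants, method="montecarlo",
                                n_null=20000, rng=rng).loc[0, "z"]
        assert abs(mc - exact) < 3 * mc_se(exact, 20000)

    def test_uniform_spread_gives_zero(self, four_plants):
        tab = make_table([[1], [1], [1], [1]], ["s1"])
        assert pt.size_preference(tab, four_plants).loc[0, "z"] == pytest.approx(0.0)

    def test_single_colonist_skipped(self, four_plants):
        tab = make_table([[0], [1], [0], [0]], ["s1"])
        res = pt.size_preference(tab, four_plants)
        assert res.loc[0, "flag"] == "skipped_min_events"
        assert np.isnan(res.loc[0, "z"])


class TestPredatorAvoidance:
    def test_toy_closed_form(self):
        """8 colonists, 7 in the 10 predator-free of 20 plants:
        z = (0.875 - 0.5) / sqrt(0.25 / 8)."""
        meta = make_meta([100.0] * 20, predator_present=[False] * 10 + [True] * 10)
        counts = np.zeros((20, 1), dtype=int)
        counts[:7, 0] = 1   # predator-free plants
        counts[10, 0] = 1   # one in a predator plant
        tab = make_table(counts, ["s1"])
        res = pt.predator_avoidance(tab, meta)
        assert res.loc[0, "observed"] == pytest.approx(0.875)
        assert res.loc[0, "z"] == pytest.approx(0.375 / np.sqrt(0.25 / 8))
        assert res.loc[0, "significant"]  # 2.121 >= 1.96

    def test_montecarlo_matches_closed_form(self, rng):
        meta = make_meta([100.0] * 20, predator_present=[False] * 10 + [True] * 10)
        counts = np.zeros((20, 1), dtype=int)
        counts[:7, 0] = 1
        counts[10, 0] = 1
        tab = make_table(counts, ["s1"])
        exact = pt.predator_avoidance(tab, meta).loc[0, "z"]
        mc = pt.predator_avoidance(tab, meta, method="montecarlo",
                                   n_null=20000, rng=rng).loc[0, "z"]
        assert abs(mc - exact) < 3 * mc_se(exact, 20000)

    def test_even_split_gives_zero(self):
        meta = make_meta([100.0] * 4, predator_present=[False, False, True, True])
        tab = make_table([[2], [2], [2], [2]], ["s1"])
        assert pt.predator_avoidance(tab, meta).loc[0, "z"] == pytest.approx(0.0)

    def test_all_predator_free_degenerate(self):
        meta = make_meta([100.0] * 4, predator_present=[False] * 4)
        tab = make_table([[1], [1], [1], [1]], ["s1"])
        res = pt.predator_avoidance(tab, meta)
        assert res.loc[0, "flag"] == "degenerate_null"
        assert np.isnan(res.loc[0, "z"])


class TestSizeSensitivity:
    def test_matches_exhaustive_hypergeometric_enumeration(self):
        """Two plants (log sizes 1 and 3), 5 introduced each, all 5
        survivors in the large plant.  The closed-form null must match
        brute-force enumeration of all C(10,5) survivor sets."""
        meta = make_meta([10.0, 1000.0], predator_present=[False, True])
        tab = make_table([[0], [5]], ["s1"], role="extinction",
                         introduced=[[5], [5]])
        res = pt.size_sensitivity(tab, meta)
        # oracle: enumerate which 5 of the 10 individuals survive
        values = np.array([1.0] * 5 + [3.0] * 5)
        means = [np.mean(values[list(c)])
                 for c in itertools.combinations(range(10), 5)]
        assert res.loc[0, "observed"] == pytest.approx(3.0)
        assert res.loc[0, "null_mean"] == pytest.approx(np.mean(means))
        assert res.loc[0, "null_sd"] == pytest.approx(np.std(means), rel=1e-9)
        assert res.loc[0, "z"] > 0

    def test_montecarlo_matches_closed_form(self, rng):
        meta = make_meta([10.0, 1000.0])
        tab = make_table([[1], [4]], ["s1"], role="extinction",
                         introduced=[[5], [5]])
        exact = pt.size_sensitivity(tab, meta).loc[0, "z"]
        mc = pt.size_sensitivity(tab, meta, method="montecarlo", n_null=5000,
                                 rng=rng).loc[0, "z"]
        assert abs(mc - exact) < 3 * mc_se(exact, 5000)

    def test_uniform_survival_gives_zero(self):
        meta = make_meta([10.0, 1000.0])
        tab = make_table([[2], [2]], ["s1"], role="extinction",
                         introduced=[[4], [4]])
        assert pt.size_sensitivity(tab, meta).loc[0, "z"] == pytest.approx(0.0)

    @pytest.mark.parametrize("surv", [[[0], [0]], [[5], [5]]])
    def test_all_or_none_survival_degenerate(self, surv):
        meta = make_meta([10.0, 1000.0])
        tab = make_table(surv, ["s1"], role="extinction",
                         introduced=[[5], [5]])
        assert pt.size_sensitivity(tab, meta).loc[0, "flag"] == "degenerate_null"

    def test_single_site_introduction_degenerate(self):
        meta = make_meta([10.0, 1000.0])
        tab = make_table([[3], [0]], ["s1"], role="extinction",
                         introduced=[[5], [0]])
        res = pt.size_sensitivity(tab, meta)
        assert res.loc[0, "flag"] == "degenerate_null"


class TestPredatorSensitivity:
    def test_toy_case_positive(self):
        """6 + 6 introduced into one predator-free and one predator plant,
        survivors 5 vs 1: survival is concentrated away from predators."""
        meta = make_meta([100.0, 100.0], predator_present=[False, True])
        tab = make_table([[5], [1]], ["s1"], role="extinction",
                         introduced=[[6], [6]])
        res = pt.predator_sensitivity(tab, meta)
        assert res.loc[0, "observed"] == pytest.approx(5 / 6)
        assert res.loc[0, "null_mean"] == pytest.approx(0.5)
        assert res.loc[0, "z"] > 0

    def test_equal_survival_gives_zero(self):
        meta = make_meta([100.0, 100.0], predator_present=[False, True])
        tab = make_table([[3], [3]], ["s1"], role="extinction",
                         introduced=[[6], [6]])
        assert pt.predator_sensitivity(tab, meta).loc[0, "z"] == pytest.approx(0.0)

    @pytest.mark.parametrize("z,expected", [(2.1, True), (1.5, False)])
    def test_significance_threshold(self, z, expected):
        row = pt.responses._row("s", "predator_sensitivity", z, 0.0, 1.0, 5)
        assert row.significant is expected


class TestInvariances:
    def test_bromeliad_order_and_unrelated_species(self):
        meta = make_meta([10.0, 100.0, 1000.0, 10000.0])
        tab = make_table([[0, 3], [1, 0], [1, 2], [2, 1]], ["s1", "s2"])
        base = pt.size_preference(tab, meta).set_index("species")["z"]
        # reverse bromeliad order
        rev_counts = tab.counts.iloc[::-1]
        rev_meta = pt.BromeliadMeta(meta.table.iloc[::-1].copy())
        rev = pt.size_preference(
            pt.CommunityTable(rev_counts, "colonization"), rev_meta
        ).set_index("species")["z"]
        assert base["s1"] == pytest.approx(rev["s1"])
        # dropping an unrelated species leaves the other unchanged
        solo = pt.size_preference(tab.subset_species(["s1"]), meta)
        assert solo.loc[0, "z"] == pytest.approx(base["s1"])


def test_combined_table_and_bh_option(null_study):
    idx = pt.compute_response_indices(
        colonization=null_study.colonization,
        extinction=null_study.extinction,
        bh_correction=True,
    )
    assert set(idx["index_kind"]) == set(pt.responses.INDEX_KINDS)
    # BH can only be more conservative than the raw threshold
    raw = pt.compute_response_indices(
        colonization=null_study.colonization,
        extinction=null_study.extinction,
    )
    assert idx["significant"].sum() <= raw["significant"].sum()
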