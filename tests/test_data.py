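"""Trees, distance matrices, community tables, scales, and survey filters."""

import numpy as np
import pandas as pd
import pytest

import phylotank as pt
from conftest import make_meta, make_table


class TestPhylogenyParsing:
    def test_parses_tips_and_hand_distances(self, three_tip_tree):
        assert three_tip_tree.tip_labels == ["A", "B", "C"]
        d = three_tip_tree.patristic_matrix()
        assert d.distance("A", "B") == pytest.approx(2.0)
        assert d.distance("A", "C") == pytest.approx(4.0)
        assert d.distance("B", "C") == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "newick",
        ["((A:1,B:-1):1,C:2);",       # negative length
         "((A:1,B):1,C:2);",          # missing length
         "((A:1,A:1):1,C:2);"],       # duplicate tips
    )
    def test_invalid_trees_rejected(self, newick):
        with pytest.raises(pt.PhylogenyError):
            pt.read_phylogeny(newick)

    def test_newick_roundtrip_preserves_distances(self, tmp_path, three_tip_tree):
        path = tmp_path / "t.nwk"
        three_tip_tree.write_newick(path)
        again = pt.read_phylogeny(path)
        assert np.allclose(
            again.patristic_matrix().values,
            three_tip_tree.patristic_matrix().values,
        )


class TestPatristicDistances:
    def test_metric_properties(self, three_tip_tree):
        d = three_tip_tree.patristic_matrix()
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_graph_shortest_path_oracle(self, seed):
        """Patristic distances equal Dijkstra on the tree-as-graph."""
        import networkx as nx

        cfg = pt.SimulationConfig(
            seed=seed, n_species=10 + 4 * seed,
            outgroup=pt.OutgroupConfig(present=seed % 2 == 0, size=3),
        )
        tree = pt.simulate_tree(cfg, np.random.default_rng(seed))
        G = nx.Graph()
        for node in tree.tree.preorder_node_iter():
            if node is tree.tree.seed_node:
                continue
            G.add_edge(id(node.parent_node), id(node), weight=node.edge.length)
        tips = {leaf.taxon.label: id(leaf) for leaf in tree.tree.leaf_node_iter()}
        d = tree.patristic_matrix()
        for i, a in enumerate(d.species):
            lengths = nx.single_source_dijkstra_path_length(G, tips[a])
            for b in d.species[i + 1:]:
                assert d.distance(a, b) == pytest.approx(lengths[tips[b]], rel=1e-9)

    def test_prune_commutes_with_distances(self, rng):
        """Distances after pruning equal the submatrix of full distances."""
        cfg = pt.SimulationConfig(seed=5, n_species=15)
        tree = pt.simulate_tree(cfg, rng)
        keep = tree.tip_labels[::2]
        pruned = tree.prune_to(keep)
        sub = tree.patristic_matrix().submatrix(sorted(keep))
        assert np.allclose(pruned.patristic_matrix().values, sub.values, atol=1e-9)


class TestCommunityTable:
    def test_round_trip_preserves_counts(self, tmp_path):
        tab = make_table([[3, 0, 1], [0, 2, 5]], ["s1", "s2", "s3"], role="survey")
        path = tmp_path / "c.csv"
        tab.to_csv(path)
        again = pt.CommunityTable.read_csv(path, "survey")
        assert (again.counts.values == tab.counts.values).all()
        assert list(again.counts.columns) == list(tab.counts.columns)

    def test_negative_and_noninteger_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_table([[1, -1]], ["s1", "s2"])
        with pytest.raises(ValueError, match="integer"):
            make_table([[1.5, 1]], ["s1", "s2"], role="colonization")

    def test_extinction_requires_dominating_introductions(self):
        with pytest.raises(ValueError, match="introduced"):
            make_table([[3, 1]], ["s1", "s2"], role="extinction",
                       introduced=[[2, 1]])
        tab = make_table([[3, 1]], ["s1", "s2"], role="extinction",
                         introduced=[[3, 2]])
        assert tab.introduced is not None


CLADES = {"ann1": "Annelida", "dipt1": "Diptera", "dipt2": "Diptera",
          "coleo1": "Coleoptera"}


class TestTaxonomicScales:
    @pytest.fixture
    def labelled_tree(self):
        return pt.read_phylogeny(
            "(((dipt1:1,dipt2:1):1,coleo1:2):3,ann1:5);", clade_labels=CLADES
        )

    @pytest.mark.parametrize(
        "scale,expected",
        [("invertebrates", ["ann1", "coleo1", "dipt1", "dipt2"]),
         ("insecta", ["coleo1", "dipt1", "dipt2"]),
         ("diptera", ["dipt1", "dipt2"])],
    )
    def test_scale_filters(self, labelled_tree, scale, expected):
        tab = make_table([[1, 1, 1, 1]], sorted(CLADES), role="survey")
        sub, subtree = pt.subset_taxonomic_scale(tab, labelled_tree, scale)
        assert sorted(sub.species) == expected
        assert sorted(subtree.tip_labels) == expected
        if scale == "invertebrates":  # identity
            assert sub is tab and subtree is labelled_tree

    def test_degenerate_scale_raises(self, labelled_tree):
        tab = make_table([[1, 0, 0, 1]], sorted(CLADES), role="survey")
        tab = tab.subset_species(["ann1", "dipt1"])
        with pytest.raises(pt.DegeneratePoolError):
            pt.subset_taxonomic_scale(tab, labelled_tree.prune_to(["ann1", "dipt1"]),
                                      "diptera")


class TestSurveyFilters:
    @pytest.fixture
    def survey(self):
        counts = np.ones((20, 3), dtype=int)
        tab = make_table(counts, ["s1", "s2", "terrestrial1"], role="survey")
        meta = make_meta([100.0] * 20)
        meta.table.loc[["b1", "b5", "b9"], "microhabitat_flag"] = True
        return tab, meta

    def test_flagged_bromeliads_removed(self, survey):
        tab, meta = survey
        out, log = pt.apply_survey_filters(tab, meta)
        assert len(out.bromeliads) == 17
        assert not {"b1", "b5", "b9"} & set(out.bromeliads)

    def test_empty_exclusions_identity(self, survey):
        tab, meta = survey
        meta.table["microhabitat_flag"] = False
        out, _ = pt.apply_survey_filters(tab, meta)
        assert (out.counts.values == tab.counts.values).all()

    def test_species_exclusion_and_unknown_id_warns(self, survey):
        tab, meta = survey
        out, log = pt.apply_survey_filters(tab, meta,
                                           exclude_species=["terrestrial1"])
        assert "terrestrial1" not in out.species
        assert any("terrestrial1" in entry for entry in log)
        with pytest.warns(UserWarning, match="ghost"):
            pt.apply_survey_filters(tab, meta, exclude_species=["ghost"])

    def test_zero_count_species_removal_is_logged_noop(self, survey):
        tab, meta = survey
        tab.counts["terrestrial1"] = 0
        out, log = pt.apply_survey_filters(tab, meta,
                                           exclude_species=["terrestrial1"])
        assert any("0 individuals" in entry for entry in log)
        assert out.counts[["s1", "s2"]].equals(tab.counts.loc[out.bromeliads,
                                                              ["s1", "s2"]])


class TestBromeliadMeta:
    def test_log_size_is_log10_capacity(self):
        meta = make_meta([10.0, 1000.0])
        assert meta.log_size().tolist() == pytest.approx([1.0, 3.0])

    def test_nonpositive_capacity_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            make_meta([10.0, 0.0])
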