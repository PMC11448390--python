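import numpy as np
import pandas as pd
import pytest

from microdyn import (
    assign_regions,
    clr_transform,
    hierarchical_partition,
    proportionality_matrix,
    pseudosimilarity_graph,
    region_abundance_series,
    region_loading_curve,
)
from microdyn.ordination import OrdinationResult


def rho_frame(values, ids):
    return pd.DataFrame(values, index=ids, columns=ids)


class TestProportionality:
    def test_shifted_copy_is_perfectly_proportional(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": x + 7.0})
        rho = proportionality_matrix(df)
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_negated_copy_is_anti_proportional(self, rng):
        x = rng.normal(size=50)
        x = x - x.mean()
        rho = proportionality_matrix(pd.DataFrame({"x": x, "y": -x}))
        assert rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(1000, 4)))
        rho = proportionality_matrix(df).to_numpy()
        off = rho[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_diagonal_is_exactly_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        assert np.allclose(np.diag(proportionality_matrix(df)), 1.0)

    def test_invariant_to_adding_constants(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 3)))
        shifted = df + [5.0, -2.0, 100.0]
        assert np.allclose(
            proportionality_matrix(df), proportionality_matrix(shifted)
        )

    def test_zero_variance_pair_flagged_nan(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.ones(10), "c": np.arange(10.0)})
        rho = proportionality_matrix(df)
        assert np.isnan(rho.loc["a", "b"])


class TestPseudosimilarityGraph:
    def test_rule_application_on_three_nodes(self):
        rho = rho_frame(
            [[1.0, 0.9, -0.7], [0.9, 1.0, 0.1], [-0.7, 0.1, 1.0]], ["A", "B", "C"]
        )
        g = pseudosimilarity_graph(rho, 0.6)
        edges = {frozenset(e) for e in g.graph.edges}
        assert edges == {frozenset({"A", "B"}), frozenset({"A", "C"})}
        assert g.components == [{"A", "B", "C"}]

    def test_subthreshold_matrix_gives_edgeless_graph(self):
        rho = rho_frame(
            [[1.0, 0.5, -0.59], [0.5, 1.0, 0.2], [-0.59, 0.2, 1.0]], list("ABC")
        )
        g = pseudosimilarity_graph(rho, 0.6)
        assert g.graph.number_of_edges() == 0
        assert g.components == []

    def test_nan_entries_count_as_no_edge(self):
        rho = rho_frame([[1.0, np.nan], [np.nan, 1.0]], ["A", "B"])
        g = pseudosimilarity_graph(rho, 0.1)
        assert g.graph.number_of_edges() == 0
        assert g.n_nan_pairs == 1

    def test_edges_monotone_decreasing_in_threshold(self, rng):
        x = rng.normal(size=(40, 12))
        rho = proportionality_matrix(pd.DataFrame(x))
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            edges = {frozenset(e) for e in pseudosimilarity_graph(rho, thr).graph.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_strict_inequality_at_threshold(self):
        rho = rho_frame([[1.0, 0.6], [0.6, 1.0]], ["A", "B"])
        assert pseudosimilarity_graph(rho, 0.6).graph.number_of_edges() == 0


class TestAssignRegions:
    def test_edgeless_graph_is_all_cloud(self):
        rho = rho_frame(np.eye(4), list("ABCD"))
        g = pseudosimilarity_graph(rho, 0.6)
        regions = assign_regions(g)
        assert set(regions.values()) == {"cloud"}

    def test_giant_component_plus_singletons(self):
        ids = list("ABCDEFGH")
        m = np.eye(8)
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            m[i, j] = m[j, i] = 0.9
        g = pseudosimilarity_graph(rho_frame(m, ids), 0.6)
        regions = assign_regions(g, k_top=1, min_component_size=3)
        assert {a for a, r in regions.items() if r == "component_1"} == {"A", "B", "C"}
        assert all(regions[a] == "cloud" for a in "DEFGH")
        assert "rest" not in regions.values()

    def test_planted_singletons_land_in_cloud(self, synthetic_subject):
        table, truth = synthetic_subject
        rho = proportionality_matrix(clr_transform(table.data, 1.0))
        g = pseudosimilarity_graph(rho, 0.6)
        regions = assign_regions(g)
        singletons = truth.index[truth.regime.isin(["rare", "white_noise"])]
        in_cloud = np.mean([regions[a] == "cloud" for a in singletons])
        assert in_cloud >= 0.9

    def test_two_planted_blocks_recovered(self):
        """Two groups of co-varying trajectories come back as two
        components (adjusted-for-chance agreement with truth >= 0.9)."""
        from sklearn.metrics import rand_score

        rng = np.random.default_rng(1)
        n = 150
        f1, f2 = rng.normal(size=(2, n))
        cols = {}
        for i in range(6):
            cols[f"X{i}"] = f1 * (1 if i % 2 else -1) + 0.3 * rng.normal(size=n)
        for i in range(6):
            cols[f"Y{i}"] = f2 * (1 if i % 2 else -1) + 0.3 * rng.normal(size=n)
        rho = proportionality_matrix(pd.DataFrame(cols))
        g = pseudosimilarity_graph(rho, 0.6)
        assert len(g.components) == 2
        labels_true = [0] * 6 + [1] * 6
        pred = []
        for name in cols:
            pred.append(0 if name in g.components[0] else 1)
        assert rand_score(labels_true, pred) >= 0.9


class TestRegionLoadingCurve:
    def _dummy_ordination(self, loadings):
        return OrdinationResult(
            coordinates=pd.DataFrame(),
            eigenvalues=np.array([1.0, 1.0]),
            proportion_explained=np.array([0.5, 0.3]),
            feature_loadings=loadings,
        )

    def test_uniform_loadings_make_regions_equal(self):
        ids = list("ABCDEF")
        m = np.eye(6)
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            m[i, j] = m[j, i] = 0.9
        loadings = pd.DataFrame({"pc1": [0.5] * 6, "pc2": [0.25] * 6}, index=ids)
        curve = region_loading_curve(
            rho_frame(m, ids), self._dummy_ordination(loadings), [0.6]
        )
        assert curve.loc[0.6, "cloud"] == pytest.approx(0.75)
        assert curve.loc[0.6, "component_1"] == pytest.approx(0.75)

    def test_component_loading_exceeds_cloud_on_synthetic(self, synthetic_subject):
        from microdyn import aitchison_pcoa

        table, _ = synthetic_subject
        rho = proportionality_matrix(clr_transform(table.data, 1.0))
        ordination = aitchison_pcoa(table)
        curve = region_loading_curve(rho, ordination, [0.5, 0.6, 0.7])
        assert curve.loc[0.6, "component_1"] > curve.loc[0.6, "cloud"]
        # stricter thresholds retain stronger co-variation
        assert curve["component_1"].is_monotonic_increasing

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            region_loading_curve(
                rho_frame(np.eye(2), ["A", "B"]),
                self._dummy_ordination(
                    pd.DataFrame({"pc1": [1, 1], "pc2": [0, 0]}, index=["A", "B"])
                ),
                [0.7, 0.5],
            )


class TestRegionAbundance:
    def test_single_region_marginalizes_to_regime_totals(self, tiny_table):
        from microdyn import regime_abundance_series

        labels = {"A": "stable_prevalent", "B": "rare"}
        regions = {"A": "component_1", "B": "component_1"}
        out = region_abundance_series(tiny_table, regions, labels)
        per_regime = regime_abundance_series(tiny_table, labels)
        totals = tiny_table.data.sum(axis=1)
        for regime in ("stable_prevalent", "rare"):
            assert np.allclose(
                out[("component_1", regime)],
                per_regime[regime].fillna(0.0) * totals,
            )

    def test_empty_regime_in_region_is_zero(self, tiny_table):
        labels = {"A": "rare", "B": "rare"}
        regions = {"A": "cloud", "B": "component_1"}
        out = region_abundance_series(tiny_table, regions, labels)
        assert (out[("cloud", "rare")] == tiny_table.data["A"]).all()

    def test_rare_only_components_excluded_when_flagged(self, tiny_table):
        labels = {"A": "rare", "B": "stable_prevalent"}
        regions = {"A": "component_1", "B": "cloud"}
        out = region_abundance_series(
            tiny_table, regions, labels, exclude_rare_only_components=True
        )
        assert "component_1" not in out.columns.get_level_values("region")


class TestHierarchicalPartition:
    def _block_similarity(self):
        m = np.zeros((6, 6))
        m[:3, :3] = 0.9
        m[3:, 3:] = 0.9
        np.fill_diagonal(m, 1.0)
        return pd.DataFrame(m, index=list("ABCDEF"), columns=list("ABCDEF"))

    @pytest.mark.parametrize("cut", [0.2, 0.5, 0.95])
    def test_two_separated_blocks(self, cut):
        # within-block distance 0.1, between-block 1.0: complete linkage
        # merges the blocks at height 1.0, so any cut below that gives 2
        labels = hierarchical_partition(self._block_similarity(), cut_height=cut)
        assert labels.nunique() == 2
        assert labels["A"] == labels["B"] == labels["C"]
        assert labels["D"] == labels["E"] == labels["F"]
        assert labels["A"] != labels["D"]

    def test_identity_similarity_keeps_singletons(self):
        sim = pd.DataFrame(np.eye(5), index=list("ABCDE"), columns=list("ABCDE"))
        labels = hierarchical_partition(sim, cut_height=0.5)
        assert labels.nunique() == 5

    def test_all_ones_collapse_to_one_cluster(self):
        sim = pd.DataFrame(np.ones((4, 4)), index=list("ABCD"), columns=list("ABCD"))
        labels = hierarchical_partition(sim, cut_height=0.5)
        assert labels.nunique() == 1

    def test_negative_cut_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_partition(self._block_similarity(), cut_height=-1)
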