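import math

import numpy as np
import pytest

from sna_qgen import network_traits as nt
from sna_qgen.io_formats import DyadicFightRecord, PenRoster
from sna_qgen.network_traits import TRAITS

from .conftest import make_graph, random_graph
from . import oracles


class TestAggregation:
    def test_durations_sum_per_unordered_dyad(self):
        recs = [DyadicFightRecord("P1", "A", "B", 10.0),
                DyadicFightRecord("P1", "B", "A", 5.0)]
        agg = nt.aggregate_fights(recs)
        assert agg == {"P1": {frozenset("AB"): 15.0}}

    def test_pens_kept_separate(self):
        recs = [DyadicFightRecord("P1", "A", "B", 10.0),
                DyadicFightRecord("P2", "X", "Y", 10.0)]
        agg = nt.aggregate_fights(recs)
        assert set(agg) == {"P1", "P2"}

    def test_empty_input(self):
        assert nt.aggregate_fights([]) == {}


class TestGraphBuilding:
    def test_non_fighters_are_isolated_nodes(self):
        g = make_graph("ABC", [("A", "B", 15.0)])
        assert g.n == 3
        assert g.graph.number_of_edges() == 1
        assert g.graph.degree("C") == 0

    def test_full_pen_without_fights(self):
        g = make_graph([f"A{i}" for i in range(18)], [])
        assert g.n == 18 and g.graph.number_of_edges() == 0

    def test_dyad_outside_roster_rejected(self):
        roster = PenRoster("P1", ("A", "B"), "female", "B1")
        with pytest.raises(ValueError, match="Z"):
            nt.build_graph(roster, {frozenset(("A", "Z")): 3.0})


class TestTraitExamples:
    """Hand-derivable values for each centrality on small pens."""

    def test_triangle_is_maximal_everywhere(self):
        g = make_graph("ABC", [("A", "B", 2.0), ("B", "C", 2.0), ("A", "C", 2.0)])
        for v in "ABC":
            assert nt.degree_centrality(g, v) == 1.0
            assert nt.betweenness_centrality(g, v) == 0.0
            assert nt.clustering_coefficient(g, v) == 1.0
            assert nt.eigenvector_centrality(g, v) == pytest.approx(1.0)

    def test_path_centralities(self):
        g = make_graph("ABC", [("A", "B", 1.0), ("B", "C", 1.0)])
        assert nt.degree_centrality(g, "B") == 1.0
        assert nt.degree_centrality(g, "A") == 0.5
        assert nt.betweenness_centrality(g, "B") == 1.0
        assert nt.closeness_centrality(g, "B") == pytest.approx(1.0)
        assert nt.closeness_centrality(g, "A") == pytest.approx(2 / 3)

    def test_degree_counts_opponents_in_large_pen(self):
        nodes = [f"A{i}" for i in range(18)]
        edges = [("A0", f"A{i}", 5.0) for i in range(1, 7)]
        g = make_graph(nodes, edges)
        assert nt.degree_centrality(g, "A0") == pytest.approx(6 / 17)

    def test_weighted_degree_sums_durations(self):
        g = make_graph("ABC", [("A", "B", 4.0), ("B", "C", 1.0)])
        assert nt.weighted_degree(g, "B") == 5.0
        assert nt.weighted_degree(g, "A") == 4.0

    def test_weighted_closeness_uses_costs(self):
        g = make_graph("ABC", [("A", "B", 4.0), ("B", "C", 1.0)])
        assert nt.closeness_centrality(g, "B") == pytest.approx(0.4)

    def test_disconnected_closeness_applies_size_correction(self):
        g = make_graph("ABCD", [("A", "B", 1.0), ("C", "D", 1.0)])
        assert nt.closeness_centrality(g, "A") == pytest.approx(1 / 3)

    def test_star_eigenvector_closed_form(self):
        g = make_graph("CABD", [("C", "A", 1.0), ("C", "B", 1.0), ("C", "D", 1.0)])
        scores = nt.eigenvector_centrality(g)
        assert scores["C"] == pytest.approx(1.0)
        for leaf in "ABD":
            assert scores[leaf] == pytest.approx(1 / math.sqrt(3), abs=1e-9)

    def test_clustering_partial_neighbourhood(self):
        edges = [("V", "a", 1.0), ("V", "b", 1.0), ("V", "c", 1.0),
                 ("a", "b", 1.0)]
        g = make_graph(["V", "a", "b", "c"], edges)
        assert nt.clustering_coefficient(g, "V") == pytest.approx(1 / 3)

    def test_isolated_node_scores_zero_on_everything(self):
        g = make_graph("ABC", [("A", "B", 7.0)])
        assert nt.degree_centrality(g, "C") == 0.0
        assert nt.weighted_degree(g, "C") == 0.0
        assert nt.betweenness_centrality(g, "C") == 0.0
        assert nt.closeness_centrality(g, "C") == 0.0
        assert nt.eigenvector_centrality(g, "C") == 0.0
        assert nt.clustering_coefficient(g, "C") == 0.0

    def test_degenerate_pen_rejected(self):
        g = make_graph("A", [])
        with pytest.raises(nt.DegeneratePenError):
            nt.degree_centrality(g, "A")

    def test_barrat_weighted_clustering(self):
        # triangle with one heavy pair: C_barrat(V) weights closed triangles
        edges = [("V", "a", 4.0), ("V", "b", 2.0), ("a", "b", 1.0)]
        g = make_graph(["V", "a", "b"], edges)
        # s=6, k=2: ((4+2)/2) / (6*1) = 0.5
        assert nt.clustering_coefficient(g, "V", clustering_mode="barrat") == \
            pytest.approx(0.5)
        assert nt.clustering_coefficient(g, "V") == 1.0


class TestOracleEquivalence:
    """All six traits vs brute-force computation on random small graphs."""

    @pytest.mark.parametrize("integer_weights", [False, True])
    def test_matches_exhaustive_oracles(self, integer_weights):
        rng = np.random.default_rng(20 + int(integer_weights))
        for _ in range(60):
            g = random_graph(rng, integer_weights=integer_weights)
            got = {
                "degree": {v: nt.degree_centrality(g, v) for v in g.graph},
                "weighted_degree": {v: nt.weighted_degree(g, v) for v in g.graph},
                "betweenness": nt.betweenness_centrality(g),
                "closeness": nt.closeness_centrality(g),
                "eigenvector": nt.eigenvector_centrality(g),
                "clustering": nt.clustering_coefficient(g),
            }
            for trait, fn in oracles.ORACLES.items():
                expect = fn(g)
                for v in g.graph:
                    assert got[trait][v] == pytest.approx(expect[v], abs=1e-9), \
                        f"{trait} mismatch at {v}"


class TestInvariants:
    def test_ranges_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            g = random_graph(rng)
            df = nt.compute_all_traits(g)
            assert df["degree"].between(0, 1).all()
            assert (df["weighted_degree"] >= 0).all()
            assert df["betweenness"].between(0, 1 + 1e-12).all()
            assert (df["closeness"] >= 0).all()
            assert df["eigenvector"].between(0, 1 + 1e-12).all()
            assert df["clustering"].between(0, 1).all()
            assert np.isfinite(df[TRAITS].to_numpy()).all()

    def test_removing_all_edges_of_a_node_zeroes_its_traits(self):
        rng = np.random.default_rng(4)
        g = random_graph(rng, max_nodes=7, p=0.8)
        v = list(g.graph.nodes)[0]
        g.graph.remove_edges_from(list(g.graph.edges(v)))
        row = nt.compute_all_traits(g).loc[v]
        assert (row[TRAITS] == 0).all()

    def test_adding_incident_edge_never_decreases_degree(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = random_graph(rng, p=0.3)
            nodes = list(g.graph.nodes)
            v = nodes[0]
            candidates = [u for u in nodes[1:] if not g.graph.has_edge(v, u)]
            if not candidates:
                continue
            d0 = nt.degree_centrality(g, v)
            w0 = nt.weighted_degree(g, v)
            g.graph.add_edge(v, candidates[0], weight=3.0)
            assert nt.degree_centrality(g, v) >= d0
            assert nt.weighted_degree(g, v) >= w0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        g = random_graph(rng, p=0.6)
        mapping = {v: f"{v}x" for v in g.graph.nodes}
        edges = [(mapping[a], mapping[b], d["weight"])
                 for a, b, d in g.graph.edges(data=True)]
        g2 = make_graph([mapping[v] for v in g.graph.nodes], edges)
        df1 = nt.compute_all_traits(g)
        df2 = nt.compute_all_traits(g2)
        for v in g.graph.nodes:
            for trait in TRAITS:
                assert df1.loc[v, trait] == pytest.approx(
                    df2.loc[mapping[v], trait], abs=1e-12)


class TestComputeAllTraits:
    def test_pen_of_isolates_is_all_zero(self):
        g = make_graph([f"A{i}" for i in range(18)], [])
        df = nt.compute_all_traits(g)
        assert (df[TRAITS].to_numpy() == 0).all()
        assert (df[[f"t_{t}" for t in TRAITS]].to_numpy() == 0).all()

    def test_transform_is_elementwise_square_root(self):
        rng = np.random.default_rng(8)
        g = random_graph(rng, p=0.7)
        df = nt.compute_all_traits(g)
        for trait in TRAITS:
            np.testing.assert_allclose(df[f"t_{trait}"] ** 2, df[trait],
                                       atol=1e-12)

    def test_inverse_weight_mode_changes_path_traits_only(self):
        g = make_graph("ABCD", [("A", "B", 5.0), ("B", "C", 1.0),
                                ("C", "D", 9.0), ("A", "C", 2.0)])
        cost = nt.compute_all_traits(g, weight_mode="cost")
        inv = nt.compute_all_traits(g, weight_mode="inverse")
        for trait in ("degree", "weighted_degree", "eigenvector", "clustering"):
            np.testing.assert_allclose(cost[trait], inv[trait])
        assert not np.allclose(cost["closeness"], inv["closeness"])
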