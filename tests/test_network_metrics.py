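"""Structural metrics: hand-derived examples and range/invariance properties."""

import math

import numpy as np
import pandas as pd
import pytest

from carenet.network_metrics import (
    UndefinedMetricError,
    clustering,
    coleman_index,
    composition,
    correlation_matrix,
    degree_centralization,
    density,
    dissimilarity_index,
    mean_in_degree_normalized,
    metrics_table,
    network_metrics,
)
from carenet.survey_io import SERVICE_TYPES

from conftest import complete_digraph, inward_star, make_network, random_digraph


class TestDensity:
    def test_complete_network(self):
        assert density(complete_digraph(5)) == 1.0

    def test_empty_network(self):
        assert density(make_network(5, [])) == 0.0

    def test_four_nodes_six_edges(self):
        # 12 ordered pairs, 6 tied
        nw = make_network(4, [(0, 1), (1, 0), (0, 2), (2, 3), (3, 1), (1, 2)])
        assert density(nw) == 0.5

    def test_undefined_below_two_nodes(self):
        with pytest.raises(UndefinedMetricError):
            density(make_network(1, []))

    def test_equals_normalized_mean_in_degree(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            nw = random_digraph(int(rng.integers(3, 15)), rng)
            assert mean_in_degree_normalized(nw) == pytest.approx(density(nw), abs=1e-12)


class TestCentralization:
    def test_inward_star_is_one(self):
        assert degree_centralization(inward_star(6)) == 1.0

    def test_complete_network_is_zero(self):
        assert degree_centralization(complete_digraph(6)) == 0.0

    def test_hand_computed_unequal_degrees(self):
        # in-degrees (4, 2, 1, 1, 0): sum of (4 - d) = 12, maximum (n-1)^2 = 16
        edges = [(1, 0), (2, 0), (3, 0), (4, 0), (0, 1), (2, 1), (0, 2), (1, 3)]
        nw = make_network(5, edges)
        assert degree_centralization(nw) == pytest.approx(12 / 16)

    def test_undefined_below_three_nodes(self):
        with pytest.raises(UndefinedMetricError):
            degree_centralization(make_network(2, [(0, 1)]))


class TestClustering:
    def test_complete_network_is_one(self):
        assert clustering(complete_digraph(5)) == 1.0

    def test_star_is_zero(self):
        assert clustering(inward_star(6)) == 0.0

    def test_triangle_plus_pendant(self):
        # triangle 0-1-2 plus pendant 3 on 0: locals 1/3, 1, 1, 0 -> mean 7/12
        nw = make_network(4, [(0, 1), (1, 2), (2, 0), (0, 3)])
        assert clustering(nw) == pytest.approx(7 / 12)


class TestReciprocity:
    def test_all_mutual(self):
        nw = make_network(3, [(0, 1), (1, 0), (1, 2), (2, 1)])
        assert reciprocity_of(nw) == 1.0

    def test_acyclic_tournament(self):
        nw = make_network(4, [(a, b) for a in range(4) for b in range(a + 1, 4)])
        assert reciprocity_of(nw) == 0.0

    def test_three_mutual_two_oneway(self):
        edges = [(0, 1), (1, 0), (2, 3), (3, 2), (4, 5), (5, 4), (0, 2), (1, 3)]
        assert reciprocity_of(make_network(6, edges)) == pytest.approx(6 / 8)

    def test_undefined_with_no_edges(self):
        with pytest.raises(UndefinedMetricError):
            reciprocity_of(make_network(4, []))


def reciprocity_of(nw):
    from carenet.network_metrics import reciprocity

    return reciprocity(nw)


class TestComposition:
    def test_single_type(self):
        comp = composition(make_network(10, [], types=["social_services"] * 10))
        assert comp["social_services"] == 1.0
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_four_distinct_types(self):
        types = ["primary_care", "social_services", "psychiatric_ward", "other"]
        comp = composition(make_network(4, [], types=types))
        assert all(comp[t] == 0.25 for t in types)

    def test_planted_mix_recovered(self):
        counts = dict(zip(SERVICE_TYPES, [13, 11, 10, 12, 21, 17, 10, 3, 3]))
        types = [t for t, c in counts.items() for _ in range(c)]
        comp = composition(make_network(100, [], types=types))
        for t, c in counts.items():
            assert comp[t] == pytest.approx(c / 100)


class TestDissimilarity:
    def test_zero_when_equal_to_reference(self):
        ref = {t: 1 / 9 for t in SERVICE_TYPES}
        assert dissimilarity_index(ref, ref) == pytest.approx(0.0)

    def test_half_for_fifty_point_excess(self):
        ref = {SERVICE_TYPES[0]: 0.5, SERVICE_TYPES[1]: 0.5}
        comp = {SERVICE_TYPES[0]: 1.0}
        assert dissimilarity_index(comp, ref) == pytest.approx(0.5)

    def test_hand_computed_l1_half(self):
        comp = {SERVICE_TYPES[0]: 0.4, SERVICE_TYPES[1]: 0.3, SERVICE_TYPES[2]: 0.3}
        ref = {SERVICE_TYPES[i]: 0.25 for i in range(4)}
        # 0.5 * (0.15 + 0.05 + 0.05 + 0.25) = 0.25
        assert dissimilarity_index(comp, ref) == pytest.approx(0.25)

    def test_rejects_non_distribution(self):
        with pytest.raises(ValueError, match="sum to 1"):
            dissimilarity_index({SERVICE_TYPES[0]: 0.8}, {SERVICE_TYPES[0]: 1.0})


class TestColeman:
    def two_type_network(self, edges_from_a):
        # type A = nodes 0-2, type B = nodes 3-7
        types = ["primary_care"] * 3 + ["social_services"] * 5
        return make_network(8, edges_from_a, types=types)

    def test_perfect_homophily(self):
        nw = self.two_type_network([(0, 1), (1, 2), (2, 0)])
        assert coleman_index(nw, "primary_care") == pytest.approx(1.0)

    def test_perfect_heterophily(self):
        nw = self.two_type_network([(0, 3), (1, 4), (2, 5)])
        assert coleman_index(nw, "primary_care") == pytest.approx(-1.0)

    def test_hand_computed_excess_homophily(self):
        # w = 3/4, e = 2/7 -> (w - e)/(1 - e) = 13/20
        nw = self.two_type_network([(0, 1), (1, 2), (2, 0), (0, 3)])
        assert coleman_index(nw, "primary_care") == pytest.approx(13 / 20)

    def test_hand_computed_mild_heterophily(self):
        # w = 1/4 < e = 2/7 -> (w - e)/e = -1/8
        nw = self.two_type_network([(0, 1), (0, 3), (1, 4), (2, 5)])
        assert coleman_index(nw, "primary_care") == pytest.approx(-1 / 8)

    def test_missing_when_no_out_edges(self):
        nw = self.two_type_network([(3, 0), (4, 1)])
        assert coleman_index(nw, "primary_care") is None

    def test_missing_when_type_spans_network(self):
        nw = make_network(4, [(0, 1)], types=["other"] * 4)
        assert coleman_index(nw, "other") is None


class TestMetricsTable:
    def test_single_network_summary_degenerates(self):
        rng = np.random.default_rng(0)
        rows, summary = metrics_table([random_digraph(8, rng)])
        assert summary.loc["density", "mean"] == summary.loc["density", "min"]
        assert summary.loc["density", "std"] == 0 or np.isnan(summary.loc["density", "std"])

    def test_mean_of_two_densities(self):
        # 4 nodes: 6 edges -> 0.5 and 12 edges -> 1.0
        a = make_network(4, [(0, 1), (1, 0), (0, 2), (2, 3), (3, 1), (1, 2)], network_id="A")
        b = complete_digraph(4, network_id="B")
        _, summary = metrics_table([a, b])
        assert summary.loc["density", "mean"] == pytest.approx(0.75)

    def test_summary_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        nets = [random_digraph(int(rng.integers(5, 20)), rng, network_id=f"G{i}") for i in range(19)]
        rows, summary = metrics_table(nets)
        for metric in ("density", "degree_centralization", "clustering"):
            vals = rows[metric].to_numpy()
            assert summary.loc[metric, "mean"] == pytest.approx(vals.mean())
            assert summary.loc[metric, "std"] == pytest.approx(vals.std(ddof=1))
            assert summary.loc[metric, "min"] == vals.min()
            assert summary.loc[metric, "max"] == vals.max()


class TestCorrelations:
    def frame(self):
        rng = np.random.default_rng(11)
        nets = [random_digraph(int(rng.integers(6, 25)), rng, network_id=f"G{i}") for i in range(19)]
        rows, _ = metrics_table(nets)
        return rows

    def test_duplicated_metric_has_r_one(self):
        rows = self.frame()
        rows["density_copy"] = rows["density"]
        m = correlation_matrix(rows, ["density", "density_copy"])
        assert m.r.loc["density", "density_copy"] == pytest.approx(1.0)

    def test_negated_metric_has_r_minus_one(self):
        rows = self.frame()
        rows["neg"] = -rows["density"]
        m = correlation_matrix(rows, ["density", "neg"])
        assert m.r.loc["density", "neg"] == pytest.approx(-1.0)

    def test_matches_hand_rolled_pearson(self):
        rows = self.frame()
        m = correlation_matrix(rows, ["density", "clustering"])
        x = rows["density"].to_numpy()
        y = rows["clustering"].to_numpy()
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert m.r.loc["density", "clustering"] == pytest.approx(r_hand, abs=1e-12)

    def test_constant_metric_reported_missing(self):
        rows = self.frame()
        rows["const"] = 0.3
        m = correlation_matrix(rows, ["density", "const"])
        assert "const" in m.dropped
        assert np.isnan(m.r.loc["density", "const"])

    def test_symmetry_and_unit_diagonal(self):
        rows = self.frame()
        m = correlation_matrix(rows, ["n_services", "density", "clustering", "degree_centralization"])
        assert np.allclose(m.r, m.r.T, equal_nan=True)
        assert np.allclose(np.diag(m.r), 1.0)


class TestProperties:
    def test_ranges_hold_on_random_networks(self):
        rng = np.random.default_rng(2024)
        ref = {t: 1 / 9 for t in SERVICE_TYPES}
        for _ in range(1000):
            n = int(rng.integers(3, 61))
            nw = random_digraph(n, rng, p=float(rng.uniform(0.05, 0.95)))
            m = network_metrics(nw, ref) if nw.n_edges else None
            if m is None:
                continue
            assert 0 <= m.density <= 1
            assert 0 <= m.degree_centralization <= 1
            assert 0 <= m.clustering <= 1
            assert 0 <= m.reciprocity <= 1
            assert 0 <= m.dissimilarity_index <= 1
            assert sum(m.composition.values()) == pytest.approx(1.0, abs=1e-9)
            for v in m.coleman.values():
                if v is not None and not math.isnan(v):
                    assert -1 <= v <= 1

    def test_node_order_invariance(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(4, 12))
            nw = random_digraph(n, rng)
            perm = rng.permutation(n)
            permuted = make_network(
                n,
                [],
                types=[nw.nodes[perm[i]].service_type for i in range(n)],
            )
            relabel = {f"S{perm[i]}": f"S{i}" for i in range(n)}
            permuted.edges = {(relabel[a], relabel[b]) for (a, b) in nw.edges}
            if not nw.n_edges:
                continue
            assert density(permuted) == pytest.approx(density(nw))
            assert degree_centralization(permuted) == pytest.approx(degree_centralization(nw))
            assert clustering(permuted) == pytest.approx(clustering(nw))
            for t in SERVICE_TYPES:
                a, b = coleman_index(nw, t), coleman_index(permuted, t)
                if a is None:
                    assert b is None
                else:
                    assert b == pytest.approx(a)
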