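"""Cluster enhancement and sign-flip permutation inference."""

import networkx as nx
import numpy as np
import pytest

from ssrsa.latency import RhoMap, group_tmap
from ssrsa.mesh import CorticalMesh
from ssrsa.synthetic import make_mesh
from ssrsa.tfce import (
    NullDistribution,
    build_st_graph,
    cluster_extent,
    corrected_pmap,
    group_inference,
    isocontour_check,
    signflip_null,
    tfce_transform,
    threshold_and_report,
)


def tfce_oracle(values, graph, delta_h=0.1):
    """Brute-force per-threshold component enumeration (networkx flood fill).

    Enumerates every threshold i*delta_h on the same descending grid as the
    implementation and recomputes connected components independently at each.
    """
    t = np.maximum(np.asarray(values, dtype=float).ravel(), 0.0)
    g = nx.Graph()
    g.add_nodes_from(range(t.size))
    coo = graph.adjacency.tocoo()
    g.add_edges_from(zip(coo.row.tolist(), coo.col.tolist()))
    out = np.zeros_like(t)
    tmax = t.max()
    i_max = int(tmax / delta_h) + 1
    while i_max > 0 and i_max * delta_h > tmax:
        i_max -= 1
    for i in range(i_max, 0, -1):
        h = i * delta_h
        active = [c for c in range(t.size) if t[c] >= h]
        for comp in nx.connected_components(g.subgraph(active)):
            extent = len(comp)
            for c in comp:
                out[c] += h * h * extent
    return out.reshape(np.asarray(values).shape)


@pytest.fixture(scope="module")
def grid_graph():
    """10 vertices x 5 latencies = 50-cell spatiotemporal grid."""
    mesh = make_mesh(5, 30.0, seed=2)
    return build_st_graph(mesh, 5), mesh


class TestGraph:
    def test_node_count_and_no_cross_hemisphere_edges(self, grid_graph):
        graph, mesh = grid_graph
        assert graph.n_cells == 50
        coo = graph.adjacency.tocoo()
        hemis = mesh.hemispheres
        for a, b in zip(coo.row, coo.col):
            assert hemis[a // 5] == hemis[b // 5]

    def test_temporal_links_connect_adjacent_latencies_only(self, grid_graph):
        graph, _ = grid_graph
        adj = graph.adjacency.toarray()
        # same vertex, latencies 0 and 1 linked; 0 and 2 not
        assert adj[graph.flat_index(0, 0), graph.flat_index(0, 1)]
        assert not adj[graph.flat_index(0, 0), graph.flat_index(0, 2)]


class TestClusterExtent:
    def test_cell_below_threshold_has_extent_zero(self, grid_graph):
        graph, _ = grid_graph
        values = np.zeros((10, 5))
        assert cluster_extent(values, 1.0, graph, (0, 0)) == 0

    def test_isolated_suprathreshold_cell_has_extent_one(self, grid_graph):
        graph, _ = grid_graph
        values = np.zeros((10, 5))
        values[3, 2] = 2.0
        assert cluster_extent(values, 1.0, graph, (3, 2)) == 1

    def test_two_by_two_block_has_extent_four(self, grid_graph):
        graph, mesh = grid_graph
        values = np.zeros((10, 5))
        # same vertex adjacent latencies plus a mesh-adjacent vertex
        coo = mesh.adjacency_matrix().tocoo()
        a, b = coo.row[0], coo.col[0]
        values[a, 1] = values[a, 2] = values[b, 1] = values[b, 2] = 5.0
        assert cluster_extent(values, 1.0, graph, (a, 1)) == 4


class TestTfceTransform:
    def test_all_zero_map_stays_zero(self, grid_graph):
        graph, _ = grid_graph
        out = tfce_transform(np.zeros((10, 5)), graph)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_below_first_threshold_gives_zero(self, grid_graph):
        graph, _ = grid_graph
        values = np.full((10, 5), 0.05)
        out = tfce_transform(values, graph)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_two_adjacent_cells_direct_evaluation(self, grid_graph):
        graph, mesh = grid_graph
        values = np.zeros((10, 5))
        values[0, 0] = values[0, 1] = 1.0  # temporal neighbours
        out = tfce_transform(values, graph)
        expected = sum((i * 0.1) ** 2 * 2 for i in range(10, 0, -1))
        assert out.values[0, 0] == pytest.approx(expected, rel=1e-12)
        assert out.values[0, 1] == out.values[0, 0]

    def test_negative_values_receive_zero(self, grid_graph):
        graph, _ = grid_graph
        values = np.full((10, 5), -3.0)
        np.testing.assert_array_equal(tfce_transform(values, graph).values, 0.0)

    def test_matches_oracle_on_random_maps(self, grid_graph):
        graph, _ = grid_graph
        rng = np.random.default_rng(7)
        for _ in range(10):
            values = rng.normal(scale=1.5, size=(10, 5))
            got = tfce_transform(values, graph).values
            np.testing.assert_array_equal(got, tfce_oracle(values, graph))

    def test_monotone_raising_one_cell_never_decreases_any(self, grid_graph):
        graph, _ = grid_graph
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 2, size=(10, 5))
        base = tfce_transform(values, graph).values
        bumped = values.copy()
        bumped[4, 2] += 1.0
        raised = tfce_transform(bumped, graph).values
        assert np.all(raised >= base - 1e-12)


class TestIsocontourCheck:
    def test_identity_map_passes(self, grid_graph):
        graph, _ = grid_graph
        values = np.random.default_rng(1).uniform(0, 2, (10, 5))
        assert isocontour_check(values, values, graph)

    def test_tfce_output_passes_on_random_maps(self, grid_graph):
        graph, _ = grid_graph
        rng = np.random.default_rng(3)
        for _ in range(10):
            values = rng.normal(scale=1.5, size=(10, 5))
            enhanced = tfce_transform(values, graph).values
            assert isocontour_check(values, enhanced, graph)

    def test_corrupted_enhancement_fails(self, grid_graph):
        graph, _ = grid_graph
        rng = np.random.default_rng(4)
        values = rng.uniform(0.5, 2.0, size=(10, 5))
        enhanced = tfce_transform(values, graph).values
        corrupted = enhanced.max() - enhanced  # reverses every strict ordering
        assert not isocontour_check(values, corrupted, graph)


def make_rho_maps(values):
    """(S, V, L) array -> list of RhoMaps."""
    s, v, l = values.shape
    return [
        RhoMap("L7", f"s{i}", np.arange(v), 10.0 * np.arange(l), values[i])
        for i in range(s)
    ]


class TestSignflipNull:
    def test_deterministic_given_seed(self, small_mesh):
        rng = np.random.default_rng(5)
        values = rng.uniform(-0.3, 0.3, size=(4, small_mesh.n_vertices, 3))
        maps = make_rho_maps(values)
        a = signflip_null(maps, small_mesh, n_perm=20, seed=3)
        b = signflip_null(maps, small_mesh, n_perm=20, seed=3)
        for hemi in a:
            np.testing.assert_array_equal(a[hemi].values, b[hemi].values)

    def test_identity_flips_reproduce_observed_maximum(self, small_mesh):
        rng = np.random.default_rng(6)
        values = rng.uniform(-0.3, 0.3, size=(4, small_mesh.n_vertices, 3))
        maps = make_rho_maps(values)

        class IdentityRng:
            def choice(self, options, size):
                return np.ones(size)

        nulls = signflip_null(maps, small_mesh, n_perm=1, rng=IdentityRng())
        tmap = group_tmap(maps)
        for hemi, null in nulls.items():
            keep = np.flatnonzero(small_mesh.hemispheres == hemi)
            graph = build_st_graph(small_mesh, 3, hemi)
            observed = tfce_transform(tmap.values[keep], graph).values.max()
            assert null.values[0] == pytest.approx(observed)

    def test_all_zero_rho_gives_all_zero_null(self, small_mesh):
        values = np.zeros((3, small_mesh.n_vertices, 2))
        nulls = signflip_null(make_rho_maps(values), small_mesh, n_perm=10, seed=0)
        for null in nulls.values():
            np.testing.assert_array_equal(null.values, 0.0)


class TestCorrectedPmap:
    def test_observed_above_all_nulls(self):
        null = NullDistribution("L", np.arange(1000.0), 1000, 0)
        p = corrected_pmap(np.array([[2000.0]]), null)
        assert p[0, 0] == pytest.approx(0.001)

    def test_observed_below_all_nulls_clamps_to_one(self):
        null = NullDistribution("L", np.arange(1.0, 101.0), 100, 0)
        p = corrected_pmap(np.array([[0.0]]), null)
        assert p[0, 0] == 1.0

    def test_observed_at_empirical_median(self):
        null = NullDistribution("L", np.arange(1.0, 102.0), 101, 0)
        p = corrected_pmap(np.array([[51.0]]), null)  # 50 nulls strictly above
        assert p[0, 0] == pytest.approx(51.0 / 101.0)


class TestThresholdAndReport:
    def test_empty_report_when_nothing_passes(self, grid_graph):
        graph, _ = grid_graph
        report = threshold_and_report(
            {"L": np.ones((5, 5))},
            {"L": tfce_transform(np.zeros((5, 5)), graph)},
            {"L": graph},
            10.0 * np.arange(5),
        )
        assert report.n_clusters == 0 and report.max_summed_extent == 0

    def test_single_component_extent(self):
        mesh = make_mesh(5, 30.0, seed=2)
        graph = build_st_graph(mesh, 5, "L")
        p = np.ones((5, 5))
        p[0, :] = 0.001  # vertex 0, all 5 latencies: one temporal chain
        values = np.zeros((5, 5))
        values[0, :] = 3.0
        report = threshold_and_report(
            {"L": p},
            {"L": tfce_transform(values, graph)},
            {"L": graph},
            10.0 * np.arange(5),
            alpha=0.01,
        )
        assert report.n_clusters == 1
        assert report.clusters[0].extent == 5
        assert report.max_summed_extent == 1  # one cell per latency

    def test_disjoint_components_sum_within_latency(self):
        # a 3-vertex chain and a separate 2-vertex pair, one latency
        mesh = CorticalMesh(
            ids=np.arange(6),
            hemispheres=["L"] * 6,
            coords=[[float(10 * i), 0, 0] for i in range(6)],
            edges=[[0, 1], [1, 2], [4, 5]],
        )
        graph = build_st_graph(mesh, 1, "L")
        suprathreshold = [0, 1, 2, 4, 5]
        p = np.ones((6, 1))
        values = np.zeros((6, 1))
        for c in suprathreshold:
            p[c, 0] = 0.001
            values[c, 0] = 2.0
        report = threshold_and_report(
            {"L": p},
            {"L": tfce_transform(values, graph)},
            {"L": graph},
            np.array([0.0]),
            alpha=0.01,
        )
        assert report.n_clusters == 2
        assert sorted(c.extent for c in report.clusters) == [2, 3]
        assert report.max_summed_extent == 5


class TestGroupInference:
    def test_planted_signal_detected_null_vertices_not(self, small_mesh):
        rng = np.random.default_rng(8)
        n_sub, nv, nl = 6, small_mesh.n_vertices, 4
        values = rng.uniform(-0.1, 0.1, size=(n_sub, nv, nl))
        values[:, 0, 1] += 0.6  # consistent positive rho at (vertex 0, lat 1)
        result = group_inference(
            make_rho_maps(values), small_mesh, n_perm=100, alpha=0.05, seed=1
        )
        assert result.pmaps["L"][0, 1] < 0.05
        assert result.min_p() >= 0.01  # bounded below by 1/n_perm
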