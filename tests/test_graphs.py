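import numpy as np
import pytest

import mapgraph as mg
from mapgraph.graphs import MapGraph, ModulePartition
from mapgraph.maps import ConnectivityMap
from mapgraph.zebrin import mean_geometry

from conftest import (
    all_partitions,
    oracle_assortativity,
    oracle_modularity,
    oracle_module_degree_zscore,
    oracle_participation,
    random_map_graph,
)


def graph_from_weights(w):
    n = len(w)
    pos = (np.arange(n) - n / 2 + 0.5) * 20.0
    return MapGraph(weights=np.asarray(w, dtype=float), positions_um=pos, positions_norm=pos / 3.2)


class TestGraphConstruction:
    def test_identical_columns_get_unit_weight(self):
        amps = np.random.default_rng(0).random((4, 3)) * 100
        amps[:, 1] = amps[:, 0]
        cmap = ConnectivityMap(amps, 20, np.array([-20.0, 0.0, 20.0]), mean_geometry())
        g = mg.build_correlation_graph(cmap)
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_columns_clipped_to_zero(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        amps = np.column_stack([col, col[::-1], col * 2])
        cmap = ConnectivityMap(amps, 20, np.array([-20.0, 0.0, 20.0]), mean_geometry())
        g = mg.build_correlation_graph(cmap)
        assert g.weights[0, 1] == 0.0

    def test_matches_elementwise_correlation_oracle(self, rng):
        amps = rng.random((6, 16)) * 100
        cmap = ConnectivityMap(
            amps, 20, (np.arange(16) - 8 + 0.5) * 20.0, mean_geometry()
        )
        g = mg.build_correlation_graph(cmap)
        from scipy.stats import pearsonr

        for i in range(16):
            for j in range(i + 1, 16):
                r = pearsonr(amps[:, i], amps[:, j])[0]
                assert g.weights[i, j] == pytest.approx(max(r, 0.0), abs=1e-12)

    def test_constant_column_gets_zero_weights(self, rng):
        amps = rng.random((5, 4))
        amps[:, 2] = 7.0
        cmap = ConnectivityMap(
            amps, 20, (np.arange(4) - 2 + 0.5) * 20.0, mean_geometry()
        )
        g = mg.build_correlation_graph(cmap)
        assert np.allclose(g.weights[2], 0.0)

    def test_affine_amplitude_transform_leaves_graph_unchanged(self, rng):
        amps = rng.random((6, 10)) * 100
        pos = (np.arange(10) - 5 + 0.5) * 20.0
        g1 = mg.build_correlation_graph(ConnectivityMap(amps, 20, pos, mean_geometry()))
        g2 = mg.build_correlation_graph(
            ConnectivityMap(2.5 * amps + 7.0, 20, pos, mean_geometry())
        )
        assert np.allclose(g1.weights, g2.weights, atol=1e-12)


class TestModularity:
    def test_two_disjoint_dyads_score_one_half(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        g = graph_from_weights(w)
        part = ModulePartition(labels=np.array([0, 0, 1, 1]), modularity=np.nan)
        assert mg.modularity(g, part) == pytest.approx(0.5)

    def test_matches_double_loop_oracle_on_random_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            g = random_map_graph(rng, n)
            if g.weights.sum() == 0:
                continue
            labels = rng.integers(0, 3, size=n)
            part = ModulePartition(labels=labels, modularity=np.nan)
            assert mg.modularity(g, part) == pytest.approx(
                oracle_modularity(g.weights, labels), abs=1e-12
            )

    def test_single_module_complete_graph_matches_oracle(self):
        w = 1.0 - np.eye(5)
        g = graph_from_weights(w)
        labels = np.zeros(5, dtype=int)
        part = ModulePartition(labels=labels, modularity=np.nan)
        assert mg.modularity(g, part) == pytest.approx(
            oracle_modularity(w, labels), abs=1e-12
        )


class TestLouvain:
    def test_two_disconnected_cliques_recovered_exactly(self):
        w = np.zeros((6, 6))
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        w[i, j] = 1.0
        part = mg.detect_modules(graph_from_weights(w), seed=0)
        assert part.n_modules == 2
        assert len(set(part.labels[:3])) == 1
        assert len(set(part.labels[3:])) == 1

    def test_fixed_seed_reproducible(self, rng):
        g = random_map_graph(rng, 10)
        p1 = mg.detect_modules(g, seed=5)
        p2 = mg.detect_modules(g, seed=5)
        assert np.array_equal(p1.labels, p2.labels)
        assert p1.modularity == p2.modularity

    def test_empty_graph_collapses_to_single_module(self):
        g = graph_from_weights(np.zeros((4, 4)))
        part = mg.detect_modules(g, seed=0)
        assert part.n_modules == 1

    def test_reaches_exhaustive_optimum_on_uniform_graph(self):
        w = 0.8 * (1.0 - np.eye(6))
        g = graph_from_weights(w)
        best = max(
            mg.modularity(g, ModulePartition(labels=np.array(p), modularity=np.nan))
            for p in all_partitions(6)
        )
        part = mg.detect_modules(g, seed=0)
        assert part.modularity == pytest.approx(best, abs=1e-9)


class TestNodeMetrics:
    def test_homogeneous_module_gives_zero_zscores(self):
        w = 1.0 - np.eye(4)
        g = graph_from_weights(w)
        part = ModulePartition(labels=np.zeros(4, dtype=int), modularity=np.nan)
        assert np.allclose(mg.module_degree_zscore(g, part), 0.0)

    def test_path_center_scores_above_ends(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        g = graph_from_weights(w)
        part = ModulePartition(labels=np.zeros(3, dtype=int), modularity=np.nan)
        z = mg.module_degree_zscore(g, part)
        assert z[0] < 0 < z[1] and z[2] < 0
        assert np.allclose(z, oracle_module_degree_zscore(w, [0, 0, 0]))

    def test_zscores_mean_zero_per_module(self, rng):
        g = random_map_graph(rng, 12)
        part = mg.detect_modules(g, seed=1)
        z = mg.module_degree_zscore(g, part)
        for m in np.unique(part.labels):
            idx = part.members(m)
            if idx.size >= 2 and np.std(z[idx]) > 0:
                assert np.mean(z[idx]) == pytest.approx(0.0, abs=1e-9)

    def test_participation_zero_for_intra_module_node(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        g = graph_from_weights(w)
        part = ModulePartition(labels=np.array([0, 0, 1, 1]), modularity=np.nan)
        assert np.allclose(mg.participation(g, part), 0.0)

    def test_participation_half_for_evenly_split_node(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        g = graph_from_weights(w)
        part = ModulePartition(labels=np.array([0, 0, 1]), modularity=np.nan)
        assert mg.participation(g, part)[0] == pytest.approx(0.5)

    def test_node_metrics_match_oracles_on_random_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            g = random_map_graph(rng, n)
            labels = rng.integers(0, 3, size=n)
            part = ModulePartition(labels=labels, modularity=np.nan)
            assert np.allclose(
                mg.module_degree_zscore(g, part),
                oracle_module_degree_zscore(g.weights, labels),
                atol=1e-9,
            )
            assert np.allclose(
                mg.participation(g, part),
                oracle_participation(g.weights, labels),
                atol=1e-9,
            )

    def test_participation_bounded_by_module_count(self, rng):
        g = random_map_graph(rng, 12)
        part = mg.detect_modules(g, seed=2)
        y = mg.participation(g, part)
        assert np.all(y >= -1e-12)
        assert np.all(y <= 1 - 1 / part.n_modules + 1e-12)


class TestAssortativity:
    def test_regular_graph_is_undefined(self):
        w = 1.0 - np.eye(4)
        assert np.isnan(mg.assortativity(graph_from_weights(w)))

    def test_star_graph_is_negative_and_matches_oracle(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        g = graph_from_weights(w)
        r = mg.assortativity(g)
        assert r < 0
        assert r == pytest.approx(oracle_assortativity(w), abs=1e-12)

    def test_duplicated_graph_keeps_same_value(self, rng):
        g = random_map_graph(rng, 6)
        r1 = mg.assortativity(g)
        n = g.n_nodes
        big = np.zeros((2 * n, 2 * n))
        big[:n, :n] = g.weights
        big[n:, n:] = g.weights
        r2 = mg.assortativity(graph_from_weights(big))
        assert r2 == pytest.approx(oracle_assortativity(big), abs=1e-12)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_matches_oracle_on_random_graphs(self, rng):
        for _ in range(20):
            g = random_map_graph(rng, int(rng.integers(5, 13)))
            ours = mg.assortativity(g)
            ref = oracle_assortativity(g.weights)
            if np.isnan(ref):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-9)


class TestNullModels:
    def test_single_edge_graph_returned_unchanged(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.7
        nulls = mg.null_ensemble(graph_from_weights(w), n_nulls=3, seed=0)
        assert all(np.allclose(n.weights, w) for n in nulls)
        assert all(n.warning for n in nulls)

    def test_rewiring_preserves_binary_degree_sequence(self, rng):
        g = random_map_graph(rng, 14)
        deg = np.sort((g.weights > 0).sum(axis=1))
        for null in mg.null_ensemble(g, n_nulls=5, seed=3):
            null_deg = np.sort((null.weights > 0).sum(axis=1))
            assert np.array_equal(deg, null_deg)
            # per-node degree, not just the sorted sequence
            assert np.array_equal(
                (g.weights > 0).sum(axis=1), (null.weights > 0).sum(axis=1)
            )

    def test_rewiring_preserves_total_weight_and_changes_edges(self, rng):
        g = random_map_graph(rng, 14)
        null = mg.null_ensemble(g, n_nulls=1, seed=4)[0]
        assert null.weights.sum() == pytest.approx(g.weights.sum())
        assert not np.allclose(null.weights, g.weights)

    def test_seeded_ensemble_reproducible(self, rng):
        g = random_map_graph(rng, 10)
        e1 = mg.null_ensemble(g, n_nulls=3, seed=9)
        e2 = mg.null_ensemble(g, n_nulls=3, seed=9)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.weights, b.weights)


class TestRelativeMetric:
    @pytest.mark.parametrize(
        "actual,med,expected", [(2.0, 2.0, 0.0), (4.0, 2.0, 100.0), (1.0, 2.0, -50.0)]
    )
    def test_delta_percent_arithmetic(self, actual, med, expected):
        assert mg.relative_metric(actual, [med, med, med]) == pytest.approx(expected)

    def test_zero_median_gives_undefined_marker(self):
        assert np.isnan(mg.relative_metric(1.0, [0.0, 0.0]))

    def test_all_undefined_nulls_raise(self):
        with pytest.raises(ValueError):
            mg.relative_metric(1.0, [np.nan, np.nan])


class TestFeatureVectors:
    def test_global_scheme_has_four_dimensions(self, rng):
        g = random_map_graph(rng, 10)
        part = mg.detect_modules(g, seed=0)
        assert mg.assemble_features(g, part, scheme="g_global").shape == (4,)

    def test_bilateral_scheme_has_seven_dimensions(self, rng):
        g = random_map_graph(rng, 10)
        part = mg.detect_modules(g, seed=0)
        assert mg.assemble_features(g, part, scheme="g_bilateral").shape == (7,)

    def test_symmetric_graph_gives_equal_bilateral_halves(self):
        # mirror-symmetric weights around the midline → ipsi and contra
        # medians coincide
        n = 8
        rng = np.random.default_rng(3)
        half = rng.random((n // 2, n // 2))
        half = np.triu(half, 1)
        half = half + half.T
        w = np.zeros((n, n))
        w[: n // 2, : n // 2] = half
        w[n // 2 :, n // 2 :] = half[::-1, ::-1]
        g = graph_from_weights(w)
        part = ModulePartition(
            labels=np.array([0, 0, 0, 0, 1, 1, 1, 1]), modularity=np.nan
        )
        f = mg.assemble_features(g, part, scheme="g_bilateral")
        assert f[1] == pytest.approx(f[4])
        assert f[2] == pytest.approx(f[5])

    def test_zonewise_weights_normalised_by_map_mean(self, small_cohort):
        from mapgraph.zoning import TEMPLATE_8, structural_zones

        m = small_cohort.maps[0]
        zm = mg.compute_zscore_map(
            amplitudes=m.amplitudes, noise_mean=4.5, noise_sd=3.5
        )
        labels = structural_zones(m.column_positions, m.geometry, TEMPLATE_8).labels
        w = mg.zonewise_weights(m, zm, labels, TEMPLATE_8)
        assert w.shape == (8,)
        covered = w[np.isfinite(w)]
        assert covered.size > 0 and np.all(covered >= 0)
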