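import numpy as np
import pytest

import oracles
from eegfc.connectivity import ConnectivityMatrix
from eegfc.errors import ConfigurationError, DataError
from eegfc.graphnet import (
    BinaryNetwork,
    band_threshold,
    binarize,
    clustering,
    compute_metrics,
    degree,
    global_efficiency,
    local_efficiency,
    max_spanning_threshold,
    path_length,
    regional_means,
)
from eegfc.montage import MONTAGE_19, RegionScheme
from eegfc.signal_prep import BANDS

THETA = BANDS["theta"]


def _cm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"ch{i}" for i in range(values.shape[0]))
    return ConnectivityMatrix(values, "PLI", THETA, tuple(labels), subject_id="s")


def _net(adj, labels=None):
    adj = np.asarray(adj)
    labels = labels or tuple(f"ch{i}" for i in range(adj.shape[0]))
    return BinaryNetwork(adj, 0.5, THETA, tuple(labels))


def _three_node():
    # w12=0.5, w13=0.3, w23=0.2 -> row maxima 0.5, 0.5, 0.3 -> threshold 0.3
    return _cm([[0, 0.5, 0.3], [0.5, 0, 0.2], [0.3, 0.2, 0]])


COMPLETE_19 = _net(1 - np.eye(19, dtype=int), MONTAGE_19)
PATH_3 = _net([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
TRIANGLE = _net([[0, 1, 1], [1, 0, 1], [1, 1, 0]])


class TestThreshold:
    def test_three_node_worked_example(self):
        m = _three_node()
        assert max_spanning_threshold(m) == pytest.approx(0.3)
        # brute force: largest candidate weight leaving no isolated node
        weights = sorted({0.5, 0.3, 0.2}, reverse=True)
        best = None
        for t in weights:
            a = (m.values >= t).astype(int)
            np.fill_diagonal(a, 0)
            if np.all(a.sum(axis=1) > 0):
                best = t
                break
        assert best == pytest.approx(0.3)

    def test_all_equal_weights(self):
        v = np.full((4, 4), 0.7)
        np.fill_diagonal(v, 0.0)
        assert max_spanning_threshold(_cm(v)) == pytest.approx(0.7)

    def test_min_of_row_maxima_on_random(self, rng):
        v = rng.random((6, 6))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        m = _cm(v)
        off = v + np.where(np.eye(6), -np.inf, 0.0)
        assert max_spanning_threshold(m) == pytest.approx(off.max(axis=1).min())

    def test_isolated_node_impossible(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.5
        with pytest.raises(DataError):
            max_spanning_threshold(_cm(v))

    def test_binarizing_at_threshold_no_isolates_and_above_isolates(self, rng):
        v = rng.random((8, 8))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        m = _cm(v)
        t = max_spanning_threshold(m)
        net = binarize(m, t)
        assert np.all(net.adjacency.sum(axis=1) >= 1)
        above = binarize(m, t + 1e-9)
        assert np.any(above.adjacency.sum(axis=1) == 0)


class TestBandThreshold:
    def test_single_subject_reduces(self):
        m = _three_node()
        assert band_threshold([m], "per_subject_min") == max_spanning_threshold(m)
        assert band_threshold([m], "group_mean") == max_spanning_threshold(m)

    def test_identical_subjects_both_modes(self):
        m = _three_node()
        for mode in ("per_subject_min", "group_mean"):
            assert band_threshold([m, m], mode) == pytest.approx(0.3)

    def test_three_subject_hand_computed_min(self):
        # per-subject no-isolated-node thresholds: 0.3, 0.2, 0.6 -> min 0.2
        ms = [
            _three_node(),
            _cm([[0, 0.9, 0.2], [0.9, 0, 0.1], [0.2, 0.1, 0]]),
            _cm([[0, 0.6, 0.6], [0.6, 0, 0.6], [0.6, 0.6, 0]]),
        ]
        assert band_threshold(ms, "per_subject_min") == pytest.approx(0.2)

    def test_unknown_mode(self):
        with pytest.raises(ConfigurationError):
            band_threshold([_three_node()], "banana")


class TestBinarize:
    def test_threshold_zero_complete(self):
        v = np.full((4, 4), 0.1)
        np.fill_diagonal(v, 0.0)
        net = binarize(_cm(v), 0.0)
        assert np.array_equal(net.adjacency, (1 - np.eye(4)).astype(int))

    def test_above_max_empty_or_validated_error(self):
        m = _three_node()
        net = binarize(m, 0.9)
        assert net.adjacency.sum() == 0
        with pytest.raises(DataError):
            binarize(m, 0.9, validate=True)

    def test_three_node_at_threshold(self):
        net = binarize(_three_node(), 0.3)  # >= rule keeps the 0.3 edge
        assert sorted(map(tuple, np.argwhere(np.triu(net.adjacency)))) == [(0, 1), (0, 2)]
        assert list(net.adjacency.sum(axis=1)) == [2, 1, 1]


class TestMetricsExamples:
    def test_complete_graph(self):
        gm = compute_metrics(COMPLETE_19)
        assert np.all(gm.node_degree == 18)
        assert gm.mean_degree == 18
        assert gm.mean_clustering == 1.0
        assert gm.char_path_length == 1.0
        assert gm.global_efficiency == pytest.approx(1.0)
        assert gm.mean_local_efficiency == pytest.approx(1.0)

    def test_path_graph(self):
        gm = compute_metrics(PATH_3)
        assert list(gm.node_degree) == [1, 2, 1]
        assert gm.mean_degree == pytest.approx(4 / 3)
        assert gm.mean_clustering == 0.0
        assert gm.char_path_length == pytest.approx(4 / 3)  # (1+1+2)*2/6
        assert gm.global_efficiency == pytest.approx(5 / 6)  # (1+1+0.5)*2/6
        assert gm.mean_local_efficiency == 0.0

    def test_triangle(self):
        gm = compute_metrics(TRIANGLE)
        assert gm.mean_clustering == 1.0
        assert gm.char_path_length == 1.0

    def test_edgeless(self):
        empty = _net(np.zeros((4, 4), dtype=int))
        assert degree(empty)[1] == 0.0
        assert global_efficiency(empty) == 0.0
        with pytest.raises(DataError):
            path_length(empty)

    def test_two_disconnected_triangles_reachable_pairs_only(self):
        adj = np.zeros((6, 6), dtype=int)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = 1
        net = _net(adj)
        assert path_length(net) == pytest.approx(1.0)
        # efficiency counts unreachable pairs as zero: 12 reachable of 30 ordered
        assert global_efficiency(net) == pytest.approx(12 / 30)


class TestOracleEquivalence:
    def test_random_graphs_match_brute_force(self, rng):
        """Nodal and global parameters agree exactly with exhaustive loops."""
        for _ in range(100):
            n = int(rng.integers(2, 9))
            adj = oracles.random_adjacency(rng, n, rng.uniform(0.15, 0.9))
            net = _net(adj)
            k, mean_k = degree(net)
            assert list(k) == oracles.degrees(adj)
            c, _ = clustering(net)
            assert np.allclose(c, oracles.clustering_coeffs(adj), atol=1e-12)
            eloc, _ = local_efficiency(net)
            assert np.allclose(eloc, oracles.local_effs(adj), atol=1e-12)
            assert global_efficiency(net) == pytest.approx(oracles.global_eff(adj), abs=1e-12)
            if adj.sum() > 0:
                assert path_length(net) == pytest.approx(
                    oracles.char_path_length(adj), abs=1e-12
                )


class TestInvariants:
    def test_threshold_monotonicity(self, rng):
        """Lowering the threshold never decreases degree or global efficiency."""
        v = rng.random((10, 10))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        m = _cm(v)
        prev_k = None
        prev_eg = None
        for t in np.linspace(0.9, 0.0, 8):
            net = binarize(m, t)
            k = net.adjacency.sum(axis=1)
            eg = global_efficiency(net)
            if prev_k is not None:
                assert np.all(k >= prev_k)
                assert eg >= prev_eg - 1e-12
            prev_k, prev_eg = k, eg

    def test_relabeling_invariance(self, rng):
        adj = oracles.random_adjacency(rng, 8, 0.4)
        perm = rng.permutation(8)
        net, pnet = _net(adj), _net(adj[np.ix_(perm, perm)])
        gm, pgm = compute_metrics(net), compute_metrics(pnet)
        assert gm.mean_degree == pgm.mean_degree
        assert gm.mean_clustering == pytest.approx(pgm.mean_clustering)
        assert gm.global_efficiency == pytest.approx(pgm.global_efficiency)
        assert np.allclose(np.sort(gm.node_degree), np.sort(pgm.node_degree))


class TestRegional:
    def test_complete_graph_uniform_regions(self):
        gm = compute_metrics(COMPLETE_19)
        regional = regional_means(gm, MONTAGE_19)
        assert set(regional) == {"frontal", "temporal", "parietal", "occipital", "central"}
        for vals in regional.values():
            assert vals["K"] == 18.0
            assert vals["C"] == 1.0
            assert vals["E_loc"] == pytest.approx(1.0)

    def test_occipital_means_only_o1_o2(self, rng):
        adj = oracles.random_adjacency(rng, 19, 0.3)
        net = _net(adj, MONTAGE_19)
        gm = compute_metrics(net)
        regional = regional_means(gm, MONTAGE_19)
        idx = [MONTAGE_19.index("O1"), MONTAGE_19.index("O2")]
        assert regional["occipital"]["K"] == pytest.approx(gm.node_degree[idx].mean())

    def test_unmapped_channel_rejected(self):
        gm = compute_metrics(_net(np.array([[0, 1], [1, 0]]), ("X99", "O1")))
        with pytest.raises(ConfigurationError):
            regional_means(gm, ("X99", "O1"))

    def test_default_partition_is_canonical(self):
        scheme = RegionScheme()
        assert scheme.regions["frontal"] == ("Fp1", "Fp2", "F3", "F4", "Fz")
        assert scheme.regions["occipital"] == ("O1", "O2")
        for ch in MONTAGE_19:
            scheme.region_of(ch)  # every montage channel mapped
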