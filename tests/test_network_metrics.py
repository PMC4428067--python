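"""Weighted graph measures against brute-force and library oracles."""
import numpy as np
import pytest

from netfluct import (SensorLayout, SyncMatrixSeries, average_windows,
                      group_summary, metric_series, node_outreach,
                      node_strength, shortest_path_stats, weighted_clustering)

from conftest import make_metrics


def random_weight_matrix(rng, n, density=1.0):
    W = rng.uniform(0.05, 1.0, size=(n, n))
    if density < 1.0:
        W[rng.random((n, n)) > density] = 0.0
    W = np.triu(W, k=1)
    return W + W.T


def floyd_warshall(lengths):
    D = lengths.copy()
    n = D.shape[0]
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def clustering_triple_loop(W):
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    wh = W / wmax
    out = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(W[i])
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                acc += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
        out[i] = acc / (k * (k - 1))
    return out


class TestNodeStrength:
    def test_uniform_triangle(self):
        W = 0.4 * (np.ones((3, 3)) - np.eye(3))
        assert np.allclose(node_strength(W), 0.8)

    def test_star_graph(self):
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 1.0
        assert np.allclose(node_strength(W), [3.0, 1.0, 1.0, 1.0])

    def test_matches_row_sum_loop(self, rng):
        W = random_weight_matrix(rng, 6)
        oracle = [sum(W[i, j] for j in range(6)) for i in range(6)]
        assert np.allclose(node_strength(W), oracle, atol=1e-12)

    @pytest.mark.parametrize("bad", [
        np.array([[0.0, 1.0], [2.0, 0.0]]),     # asymmetric
        np.array([[0.0, -1.0], [-1.0, 0.0]]),   # negative
        np.array([[1.0, 0.5], [0.5, 0.0]]),     # nonzero diagonal
    ])
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            node_strength(bad)


class TestNodeOutreach:
    def test_single_link_arithmetic(self):
        lay = SensorLayout(("a", "b"), [[0, 0, 0], [0.1, 0, 0]])
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert np.allclose(node_outreach(W, lay), 0.05)

    def test_zero_weights_zero_outreach(self, layout6):
        assert np.allclose(node_outreach(np.zeros((6, 6)), layout6), 0.0)

    def test_matches_pairwise_loop(self, rng, layout6):
        W = random_weight_matrix(rng, 6)
        c = layout6.coords
        oracle = [sum(W[i, j] * np.linalg.norm(c[i] - c[j]) for j in range(6))
                  for i in range(6)]
        assert np.allclose(node_outreach(W, layout6), oracle, atol=1e-12)


class TestWeightedClustering:
    def test_uniform_triangle_fully_clustered(self):
        W = 0.7 * (np.ones((3, 3)) - np.eye(3))
        assert np.allclose(weighted_clustering(W), 1.0)

    def test_path_center_has_no_triangle(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.8
        W[1, 2] = W[2, 1] = 0.6
        assert weighted_clustering(W)[1] == 0.0

    def test_matches_triple_enumeration(self, rng):
        W = random_weight_matrix(rng, 6, density=0.8)
        assert np.allclose(weighted_clustering(W),
                           clustering_triple_loop(W), atol=1e-12)

    def test_matches_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        W = random_weight_matrix(rng, 7, density=0.7)
        g = nx.from_numpy_array(W)
        ref = nx.clustering(g, weight="weight")
        ours = weighted_clustering(W)
        assert np.allclose(ours, [ref[i] for i in range(7)], atol=1e-10)


class TestShortestPathStats:
    def test_uniform_triangle(self):
        w = 0.5
        W = w * (np.ones((3, 3)) - np.eye(3))
        stats = shortest_path_stats(W)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(stats.distances[off], 1 / w)
        assert stats.sp == pytest.approx(1 / w)
        assert stats.eg == pytest.approx(w)
        assert stats.connected

    def test_two_hop_route_beats_weak_direct_link(self):
        W = np.array([[0.0, 1.0, 0.1],
                      [1.0, 0.0, 1.0],
                      [0.1, 1.0, 0.0]])
        stats = shortest_path_stats(W)
        assert stats.distances[0, 2] == pytest.approx(2.0)  # via the middle

    def test_matches_floyd_warshall(self, rng):
        for _ in range(5):
            W = random_weight_matrix(rng, 7, density=0.6)
            with np.errstate(divide="ignore"):
                lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
            oracle = floyd_warshall(lengths)
            stats = shortest_path_stats(W)
            assert np.allclose(stats.distances, oracle)

    def test_isolated_node_flagged_and_excluded(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        stats = shortest_path_stats(W)
        assert not stats.connected
        assert stats.sp == pytest.approx(1.0)  # only the connected pair
        assert stats.eg == pytest.approx(1.0 / 3.0)  # 1 of 3 pairs reachable


class TestScalingLaws:
    def test_metric_scaling_under_weight_rescaling(self, rng, layout6):
        W = random_weight_matrix(rng, 6)
        alpha = 3.7
        assert np.allclose(node_strength(alpha * W),
                           alpha * node_strength(W))
        assert np.allclose(node_outreach(alpha * W, layout6),
                           alpha * node_outreach(W, layout6))
        a, b = shortest_path_stats(W), shortest_path_stats(alpha * W)
        assert b.sp == pytest.approx(a.sp / alpha)
        assert b.eg == pytest.approx(a.eg * alpha)
        # clustering is invariant: weights are normalized by their maximum
        assert np.allclose(weighted_clustering(alpha * W),
                           weighted_clustering(W))

    def test_single_weight_increase_monotone(self, rng):
        W = random_weight_matrix(rng, 5)
        W2 = W.copy()
        W2[1, 3] = W2[3, 1] = W[1, 3] + 0.5
        assert (node_strength(W2) >= node_strength(W) - 1e-12).all()
        a, b = shortest_path_stats(W), shortest_path_stats(W2)
        assert (b.distances <= a.distances + 1e-12).all()


class TestMetricSeries:
    def _series(self, mats, boundary=500.0):
        nw = mats.shape[0]
        windows = [(50.0 * w, 50.0 * (w + 1)) for w in range(nw)]
        regimes = np.array(["I" if a >= boundary else "MM"
                            for a, _ in windows])
        return SyncMatrixSeries(windows=windows, matrices=mats, band="alpha",
                                regimes=regimes, subject_id="s",
                                group="young")

    def test_toy_series_matches_per_window_computation(self, rng):
        lay = SensorLayout(tuple("abcd"),
                           rng.uniform(-0.1, 0.1, size=(4, 3)))
        mats = np.stack([random_weight_matrix(rng, 4) for _ in range(3)])
        m = metric_series(self._series(mats), lay)
        for w in range(3):
            assert np.allclose(m.node_strength[w], node_strength(mats[w]))
            assert np.allclose(m.node_outreach[w],
                               node_outreach(mats[w], lay))
            stats = shortest_path_stats(mats[w])
            assert m.network["SP"][w] == pytest.approx(stats.sp)
            assert m.network["Eg"][w] == pytest.approx(stats.eg)
            assert m.network["S"][w] == pytest.approx(
                node_strength(mats[w]).mean())

    def test_constant_series_constant_traces(self, rng, layout6):
        W = random_weight_matrix(rng, 6)
        mats = np.repeat(W[None], 30, axis=0)
        m = metric_series(self._series(mats), layout6)
        for name in ("S", "O", "Cw", "Eg", "SP"):
            assert np.ptp(m.network[name]) < 1e-12
        assert m.n_windows == 30


class TestAverageWindows:
    def test_default_span_sizes(self):
        m = make_metrics(np.arange(1, 31, dtype=float))
        assert (m.regimes == "MM").sum() == 10
        assert (m.regimes == "I").sum() == 20

    def test_linear_ramp_span_means(self):
        m = make_metrics(np.arange(1, 31, dtype=float))
        assert average_windows(m, "MM")["S"] == pytest.approx(5.5)
        assert average_windows(m, "I")["S"] == pytest.approx(20.5)
        assert average_windows(m, "MM+I")["S"] == pytest.approx(15.5)

    def test_constant_trace_all_spans_equal(self):
        m = make_metrics(np.full(30, 2.5))
        for span in ("MM", "I", "MM+I"):
            assert average_windows(m, span)["S"] == pytest.approx(2.5)

    def test_unknown_span_rejected(self):
        with pytest.raises(ValueError):
            average_windows(make_metrics(np.ones(30)), "XX")


class TestGroupSummary:
    def test_identical_subjects_zero_sem(self):
        ms = [make_metrics(np.ones(30), subject_id=f"s{i}") for i in range(2)]
        gs = group_summary(ms)
        assert np.allclose(gs.groups["young"].window_sem["S"], 0.0)

    def test_closed_form_sem(self):
        ms = [make_metrics(np.full(30, v), subject_id=f"s{v}")
              for v in (1.0, 2.0, 3.0)]
        gs = group_summary(ms)
        g = gs.groups["young"]
        assert np.allclose(g.window_mean["S"], 2.0)
        assert np.allclose(g.window_sem["S"], 1.0 / np.sqrt(3))

    def test_group_relabeling_swaps_summaries(self):
        a = [make_metrics(np.full(30, 1.0), group="young", subject_id="a1"),
             make_metrics(np.full(30, 1.0), group="young", subject_id="a2")]
        b = [make_metrics(np.full(30, 5.0), group="old", subject_id="b1"),
             make_metrics(np.full(30, 5.0), group="old", subject_id="b2")]
        gs = group_summary(a + b)
        swapped = group_summary(
            [make_metrics(np.full(30, 5.0), group="young", subject_id="c1"),
             make_metrics(np.full(30, 5.0), group="young", subject_id="c2"),
             make_metrics(np.full(30, 1.0), group="old", subject_id="d1"),
             make_metrics(np.full(30, 1.0), group="old", subject_id="d2")])
        assert np.allclose(gs.groups["young"].window_mean["S"],
                           swapped.groups["old"].window_mean["S"])

    def test_single_subject_sem_flagged_undefined(self):
        gs = group_summary([make_metrics(np.ones(30))])
        g = gs.groups["young"]
        assert not g.sem_defined
        assert np.isnan(g.window_sem["S"]).all()
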