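import numpy as np
import pytest

from plinet.network import (WeightedNetwork, build_network, char_path_length,
                            global_clustering, nodal_clustering, randomize_weights,
                            small_world)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def clustering_bruteforce(w: np.ndarray) -> np.ndarray:
    """Triple-loop triangle enumeration of the Onnela coefficient."""
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(w[i])
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def random_net(rng, n=10, zero_frac=0.0):
    w = rng.uniform(0.05, 1.0, (n, n))
    if zero_frac:
        mask = rng.random((n, n)) < zero_frac
        w[mask] = 0.0
    w = np.triu(w, 1)
    w = w + w.T
    return WeightedNetwork(weights=w, labels=[f"n{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_identity_copy(self, rng):
        net = random_net(rng)
        rebuilt = build_network(net.weights)
        np.testing.assert_array_equal(rebuilt.weights, net.weights)

    def test_zero_edge_accepted(self):
        w = np.array([[0, 0.5, 0.0], [0.5, 0, 0.2], [0.0, 0.2, 0]])
        assert build_network(w).n == 3

    def test_asymmetric_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.5
        with pytest.raises(ValueError):
            build_network(w)

    def test_59_nodes(self, rng):
        assert random_net(rng, n=59).n == 59


class TestNodalClustering:
    def test_uniform_triangle(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0)
        c = nodal_clustering(build_network(w))
        np.testing.assert_allclose(c, 0.5, atol=1e-12)

    def test_path_center_zero_triangles(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        c = nodal_clustering(build_network(w))
        assert c[1] == 0.0

    def test_star_all_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.8
        np.testing.assert_array_equal(nodal_clustering(build_network(w)), 0.0)

    def test_matches_bruteforce_many_seeds(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            net = random_net(rng, n=10, zero_frac=0.2 if seed % 3 == 0 else 0.0)
            fast = nodal_clustering(net)
            slow = clustering_bruteforce(net.weights)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_strength_denominator_variant(self, rng):
        net = random_net(rng, n=6)
        c = nodal_clustering(net, denominator="strength")
        s = net.weights.sum(axis=1)
        w13 = np.cbrt(net.weights)
        expected = np.diag(w13 @ w13 @ w13) / (s * (s - 1))
        valid = s * (s - 1) > 0
        np.testing.assert_allclose(c[valid], expected[valid], atol=1e-10)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            nodal_clustering(build_network(np.zeros((2, 2))))


class TestGlobalClustering:
    @pytest.mark.parametrize("w_val", [0.2, 0.5, 0.9])
    def test_uniform_complete_equals_weight(self, w_val):
        # brute-force-checked generalization of the triangle case at n = 5
        w = np.full((5, 5), w_val)
        np.fill_diagonal(w, 0)
        net = build_network(w)
        assert global_clustering(net) == pytest.approx(w_val, abs=1e-10)
        np.testing.assert_allclose(clustering_bruteforce(w), w_val, atol=1e-10)

    def test_zero_network(self):
        assert global_clustering(build_network(np.zeros((4, 4)))) == 0.0

    def test_permutation_invariance(self, rng):
        net = random_net(rng, n=8)
        perm = rng.permutation(8)
        permuted = build_network(net.weights[np.ix_(perm, perm)])
        assert global_clustering(permuted) == pytest.approx(global_clustering(net),
                                                            abs=1e-12)
        np.testing.assert_allclose(nodal_clustering(permuted),
                                   nodal_clustering(net)[perm], atol=1e-12)


class TestCharPathLength:
    def test_single_edge(self):
        w = np.array([[0, 0.5], [0.5, 0]])
        assert char_path_length(build_network(w)) == pytest.approx(2.0)

    def test_uniform_triangle(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0)
        assert char_path_length(build_network(w)) == pytest.approx(2.0)

    def test_detour_beats_weak_edge(self):
        # d(a,c) = 4 via b (2+2 < 10); L = (2+2+4)/3
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        w[0, 2] = w[2, 0] = 0.1
        assert char_path_length(build_network(w)) == pytest.approx(8.0 / 3.0)

    def test_matches_floyd_warshall_many_seeds(self):
        for seed in range(100):
            rng = np.random.default_rng(seed + 1000)
            net = random_net(rng, n=10)
            d = floyd_warshall(net.weights)
            expected = d[~np.eye(10, dtype=bool)].mean()
            assert char_path_length(net) == pytest.approx(expected, abs=1e-10)

    def test_disconnected_raises(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        with pytest.raises(ValueError):
            char_path_length(build_network(w))
        # reachable mode averages over reachable pairs
        assert char_path_length(build_network(w), on_disconnected="reachable") \
            == pytest.approx(2.0)


class TestRandomizeWeights:
    def test_uniform_network_fixed_point(self):
        w = np.full((5, 5), 0.4)
        np.fill_diagonal(w, 0)
        net = build_network(w)
        np.testing.assert_array_equal(randomize_weights(net, seed=3).weights, w)

    def test_weight_multiset_preserved(self, rng):
        net = random_net(rng, n=8)
        surr = randomize_weights(net, seed=11)
        iu = np.triu_indices(8, 1)
        np.testing.assert_allclose(np.sort(net.weights[iu]), np.sort(surr.weights[iu]))
        np.testing.assert_array_equal(np.diag(surr.weights), 0)
        np.testing.assert_array_equal(surr.weights, surr.weights.T)

    def test_seed_determinism(self, rng):
        net = random_net(rng, n=8)
        a = randomize_weights(net, seed=5).weights
        b = randomize_weights(net, seed=5).weights
        np.testing.assert_array_equal(a, b)


class TestSmallWorld:
    def test_uniform_complete_sw_exactly_one(self):
        w = np.full((6, 6), 0.3)
        np.fill_diagonal(w, 0)
        m = small_world(build_network(w), n_surrogates=10, seed=0)
        assert m.SW == pytest.approx(1.0, abs=1e-12)
        assert m.C_rand == pytest.approx(m.C)
        assert m.L_rand == pytest.approx(m.L)

    def test_iid_complete_sw_near_one(self):
        rng = np.random.default_rng(42)
        net = random_net(rng, n=20)
        m = small_world(net, n_surrogates=50, seed=1)
        assert 0.9 <= m.SW <= 1.1

    def test_scale_invariance(self, rng):
        net = random_net(rng, n=8)
        m1 = small_world(net, n_surrogates=20, seed=2)
        scaled = WeightedNetwork(weights=0.5 * net.weights, labels=net.labels)
        m2 = small_world(scaled, n_surrogates=20, seed=2)
        assert m2.C == pytest.approx(0.5 * m1.C, rel=1e-10)
        assert m2.L == pytest.approx(2.0 * m1.L, rel=1e-10)
        assert m2.SW == pytest.approx(m1.SW, rel=1e-10)

    def test_permutation_leaves_sw_unchanged(self, rng):
        net = random_net(rng, n=7)
        perm = rng.permutation(7)
        permuted = build_network(net.weights[np.ix_(perm, perm)])
        m1 = small_world(net, n_surrogates=30, seed=9)
        m2 = small_world(permuted, n_surrogates=30, seed=9)
        # surrogate draws differ by permutation, so compare loosely
        assert m1.C == pytest.approx(m2.C, rel=1e-10)
        assert m1.L == pytest.approx(m2.L, rel=1e-10)
        assert m1.SW == pytest.approx(m2.SW, rel=0.05)

    def test_scale_law_clustering_linear_path_inverse(self, rng):
        net = random_net(rng, n=6)
        for c in (0.25, 2.0):
            scaled = WeightedNetwork(weights=np.clip(c * net.weights, 0, None),
                                     labels=net.labels)
            assert global_clustering(scaled) == pytest.approx(
                c * global_clustering(net), rel=1e-10)
            assert char_path_length(scaled) == pytest.approx(
                char_path_length(net) / c, rel=1e-10)
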