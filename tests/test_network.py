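import numpy as np
import pytest
from hypothesis import given, strategies as st

import isletca as ic
from isletca import network as net

from conftest import markov_burst


class TestBinarize:
    def test_strict_threshold(self):
        b = ic.binarize(np.array([[0.25, 0.15, 0.2, 0.0]]))
        np.testing.assert_array_equal(b.matrix, [[1, 0, 0, 0]])

    def test_all_zero_trace(self):
        b = ic.binarize(np.zeros((1, 10)))
        assert b.matrix.sum() == 0

    def test_active_time(self):
        b = ic.binarize(np.array([[0.5, 0.5, 0.0, 0.5]]))
        np.testing.assert_array_equal(b.active_time_frames(), [3.0])


class TestCoactivityPair:
    def test_identical_vectors_give_one(self):
        a = np.r_[np.ones(200), np.zeros(200)].astype(np.uint8)
        assert ic.coactivity_pair(a, a) == pytest.approx(1.0)

    def test_half_overlap_gives_half(self):
        a = np.zeros(2400, np.uint8)
        b = np.zeros(2400, np.uint8)
        a[:200] = 1
        b[100:300] = 1
        assert ic.coactivity_pair(a, b) == pytest.approx(0.5)

    def test_disjoint_gives_zero(self):
        a = np.zeros(400, np.uint8)
        b = np.zeros(400, np.uint8)
        a[:200] = 1
        b[200:] = 1
        assert ic.coactivity_pair(a, b) == 0.0

    def test_silent_cell_gives_zero(self):
        assert ic.coactivity_pair(np.zeros(10), np.ones(10)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ic.coactivity_pair(np.ones(5), np.ones(6))


class TestShuffleNull:
    def test_identical_bursty_vectors_significant(self):
        rng = np.random.default_rng(0)
        a = markov_burst(2400, rng)
        _, _, sig = ic.shuffle_null(a, a, n_shuffles=1000, rng=1)
        assert sig

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError):
            ic.shuffle_null(np.ones(10), np.ones(10), n_shuffles=0)

    def test_all_zero_vector_not_significant(self):
        m, s, sig = ic.shuffle_null(np.zeros(100), np.ones(100), rng=0)
        assert (m, s, sig) == (0.0, 0.0, False)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(3)
        a, b = markov_burst(1000, rng), markov_burst(1000, rng)
        r1 = ic.shuffle_null(a, b, n_shuffles=500, rng=42)
        r2 = ic.shuffle_null(a, b, n_shuffles=500, rng=42)
        assert r1 == r2

    def test_independent_sparse_pairs_rarely_flagged(self):
        # chance-coactivity calibration at p_active = 0.1
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            a = (rng.random(1200) < 0.1).astype(np.uint8)
            b = (rng.random(1200) < 0.1).astype(np.uint8)
            hits += ic.shuffle_null(a, b, n_shuffles=200, rng=rng)[2]
        assert hits / 200 <= 0.06


def brute_coactivity(B):
    n = B.shape[0]
    C = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ti = B[i].sum()
            tj = B[j].sum()
            tij = int(np.logical_and(B[i], B[j]).sum())
            C[i, j] = tij / np.sqrt(ti * tj) if ti and tj else 0.0
    return C


class TestCoactivityMatrix:
    def test_three_cell_hand_computed(self):
        B = np.array([
            [1, 1, 1, 1, 0, 0, 0, 0],
            [1, 1, 0, 0, 1, 1, 0, 0],
            [0, 0, 0, 0, 0, 0, 1, 1],
        ], dtype=np.uint8)
        res = ic.coactivity_matrix(B, n_shuffles=10, rng=0)
        expected = np.array([
            [1.0, 0.5, 0.0],
            [0.5, 1.0, 0.0],
            [0.0, 0.0, 1.0],
        ])
        np.testing.assert_allclose(res.C, expected)
        assert res.c_islet == pytest.approx(np.mean([0.5, 0.0, 0.0, 0.5, 0.0, 0.0]))

    def test_identical_cells_fully_connected(self):
        row = np.r_[np.ones(100), np.zeros(100)].astype(np.uint8)
        res = ic.coactivity_matrix(np.tile(row, (4, 1)), n_shuffles=100, rng=0)
        np.testing.assert_allclose(res.C, 1.0)
        assert res.c_islet == pytest.approx(1.0)
        assert res.connectivity_class == "high"

    def test_disjoint_cells_unconnected(self):
        B = np.zeros((3, 300), np.uint8)
        for i in range(3):
            B[i, i * 100:(i + 1) * 100] = 1
        res = ic.coactivity_matrix(B, n_shuffles=100, rng=0)
        assert res.c_islet == 0.0

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError):
            ic.coactivity_matrix(np.ones((1, 10), np.uint8), rng=0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(2, 6)
            B = (rng.random((n, rng.integers(10, 40))) < 0.4).astype(np.uint8)
            res = ic.coactivity_matrix(B, n_shuffles=5, rng=0)
            np.testing.assert_allclose(res.C, brute_coactivity(B), atol=1e-12)

    @given(st.integers(0, 2**16))
    def test_invariant_to_common_circular_shift(self, seed):
        rng = np.random.default_rng(seed)
        B = (rng.random((4, 60)) < 0.3).astype(np.uint8)
        shift = int(rng.integers(0, 60))
        res1 = ic.coactivity_matrix(B, n_shuffles=5, rng=0)
        res2 = ic.coactivity_matrix(np.roll(B, shift, axis=1), n_shuffles=5, rng=0)
        np.testing.assert_allclose(res1.C, res2.C, atol=1e-12)


class TestConnectivityClass:
    @pytest.mark.parametrize("value,expected", [
        (0.3, "low"), (0.5, "low"), (0.505, "medium"), (0.6, "medium"),
        (0.75, "medium"), (0.755, "high"), (0.802, "high"), (1.0, "high"),
    ])
    def test_bins(self, value, expected):
        assert ic.connectivity_class(value) == expected


def _result_with(C, significant):
    n = C.shape[0]
    return net.CoactivityResult(
        C=C, significant=significant, null_mean=np.zeros((n, n)),
        null_sd=np.zeros((n, n)), n_shuffles=1, c_islet=0.0,
        connectivity_class="low",
    )


class TestHubs:
    def _ring(self, strong_count):
        # cell 0 has 10 significant partners, `strong_count` of them >= 0.8
        n = 11
        C = np.full((n, n), 0.5)
        np.fill_diagonal(C, 1.0)
        sig = np.zeros((n, n), bool)
        sig[0, 1:] = sig[1:, 0] = True
        C[0, 1:strong_count + 1] = C[1:strong_count + 1, 0] = 0.9
        return _result_with(C, sig)

    def test_criterion_nine_of_ten(self):
        assert ic.identify_hubs_criterion(self._ring(9))[0]

    def test_criterion_seven_of_ten(self):
        assert not ic.identify_hubs_criterion(self._ring(7))[0]

    def test_no_significant_partners_never_hub(self):
        C = np.eye(3)
        res = _result_with(C, np.zeros((3, 3), bool))
        assert not ic.identify_hubs_criterion(res).any()

    def test_top10_counts(self):
        rng = np.random.default_rng(1)
        B = (rng.random((50, 400)) < 0.3).astype(np.uint8)
        res = ic.coactivity_matrix(B, n_shuffles=50, rng=0)
        labels = ic.identify_hubs_top10(res)
        assert labels.sum() == 5

    def test_top10_highest_degree_always_flagged(self):
        n = 10
        C = np.eye(n)
        sig = np.zeros((n, n), bool)
        for j in range(1, n):  # cell 0 connected to everyone
            sig[0, j] = sig[j, 0] = True
        sig[1, 2] = sig[2, 1] = True
        res = _result_with(C, sig)
        labels = ic.identify_hubs_top10(res)
        assert labels[0] and labels.sum() == 1

    def test_planted_high_participation_enriched(self, clean_result, clean_sim):
        _, _, _, _, truth = clean_sim
        hubs = clean_result.hubs_criterion
        included = clean_result.included
        base_rate = hubs[included].mean()
        planted_rate = hubs[truth.high_participation].mean()
        assert planted_rate >= 2 * base_rate > 0


class TestExportNetwork:
    def _toy(self):
        row = np.r_[np.ones(50), np.zeros(50)].astype(np.uint8)
        return ic.coactivity_matrix(np.tile(row, (3, 1)), n_shuffles=50, rng=0,
                                    cell_ids=["a", "b", "c"])

    def test_full_edge_count(self):
        nodes, edges = ic.export_network(self._toy())
        assert len(edges) == 3  # n(n-1)/2
        assert set(nodes.cell_id) == {"a", "b", "c"}

    def test_significant_only_filter(self):
        res = self._toy()
        res.significant[:] = False
        _, edges = ic.export_network(res, significant_only=True)
        assert len(edges) == 0

    def test_centroids_joined(self):
        cent = ic.CellCentroids(["a", "b", "c"], [1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        nodes, _ = ic.export_network(self._toy(), cent)
        np.testing.assert_array_equal(nodes.x_px, [1, 2, 3])
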