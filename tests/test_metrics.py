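import numpy as np
import pytest

from gala.io_formats import LandmarkSet
from gala.metrics import (gmm_cluster_scores, label_consistency_accuracy,
                          landmark_mae, mutual_nearest_pairs,
                          pseudo_spot_cosine, spatial_cross_correlation)


def rigid(pts, theta, t):
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return pts @ R.T + t


class TestLabelConsistency:
    def test_identical_slices_score_one(self, rng):
        pts = rng.uniform(0, 10, size=(40, 2))
        labels = rng.integers(0, 3, size=40)
        rep = label_consistency_accuracy(pts, labels, pts, labels)
        assert rep.value == 1.0

    def test_half_flipped_labels_score_half(self):
        pts = np.arange(8, dtype=float).reshape(4, 2) * 10
        tgt = np.array(["a", "a", "b", "b"])
        src = np.array(["a", "a", "a", "a"])  # half of the pairs disagree
        rep = label_consistency_accuracy(pts, src, pts, tgt)
        assert rep.value == 0.5

    def test_mnn_pairs_match_brute_force(self, rng):
        a = rng.uniform(0, 5, size=(30, 2))
        b = rng.uniform(0, 5, size=(30, 2))
        pairs = set(map(tuple, mutual_nearest_pairs(a, b)))
        # O(n²) enumeration
        d = np.linalg.norm(a[:, None] - b[None], axis=2)
        ref = {(i, j) for i in range(30) for j in range(30)
               if d[i].argmin() == j and d[:, j].argmin() == i}
        assert pairs == ref

    def test_no_pairs_impossible_with_points(self):
        with pytest.raises(ValueError, match="mutual"):
            label_consistency_accuracy(np.zeros((0, 2)), np.array([]),
                                       np.zeros((0, 2)), np.array([]))

    def test_invariant_to_joint_rigid_motion(self, rng):
        a = rng.uniform(0, 10, (25, 2))
        b = rng.uniform(0, 10, (25, 2))
        la = rng.integers(0, 2, 25)
        lb = rng.integers(0, 2, 25)
        v1 = label_consistency_accuracy(a, la, b, lb).value
        v2 = label_consistency_accuracy(rigid(a, 0.7, [3, -2]), la,
                                        rigid(b, 0.7, [3, -2]), lb).value
        assert v1 == v2


class TestGmmScores:
    def test_separated_blobs_perfect_scores(self, rng):
        n = 60
        c1 = rng.normal(0, 0.3, size=(n, 2))
        c2 = rng.normal(50, 0.3, size=(n, 2))
        coords = np.vstack([c1, c2])
        expr = np.vstack([np.tile([5.0, 0, 1], (n, 1)),
                          np.tile([0.0, 5, 1], (n, 1))])
        expr += rng.normal(0, 0.05, size=expr.shape)
        labels = np.array(["x"] * n + ["y"] * n)
        # pooled slices: pass the same data as source and target
        rep = gmm_cluster_scores(coords, expr, coords, expr,
                                 np.concatenate([labels, labels]), K=2)
        assert rep.breakdown["ARI"] == 1.0
        assert rep.breakdown["NMI"] == 1.0

    def test_random_labels_near_zero_ari(self):
        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            coords = rng.uniform(0, 10, size=(250, 2))
            expr = rng.random((250, 5))
            labels = rng.integers(0, 2, size=500)
            rep = gmm_cluster_scores(coords, expr, coords, expr, labels,
                                     K=2, seed=seed)
            aris.append(rep.breakdown["ARI"])
        assert np.all(np.abs(aris) < 0.1)

    def test_single_blob_no_crash(self, rng):
        coords = rng.normal(0, 1, size=(50, 2))
        expr = rng.random((50, 3))
        labels = np.zeros(100, dtype=int)
        labels[50:] = 1
        rep = gmm_cluster_scores(coords, expr, coords, expr, labels, K=2)
        assert abs(rep.breakdown["ARI"]) < 0.5

    def test_k_exceeding_n_rejected(self, rng):
        coords = rng.random((3, 2))
        with pytest.raises(ValueError):
            gmm_cluster_scores(coords, coords, coords, coords,
                               np.zeros(6), K=10)


class TestSpatialCrossCorrelation:
    def test_self_correlation_limit(self, rng):
        pts = np.stack(np.meshgrid(np.arange(8.0), np.arange(8.0)),
                       axis=-1).reshape(-1, 2)
        expr = rng.random((64, 3)) + 0.1
        rep = spatial_cross_correlation(pts, expr, pts, expr,
                                        bandwidth=0.1)
        assert rep.value > 0.99

    def test_sign_flip_gives_negative_scores(self, rng):
        pts = rng.uniform(0, 10, size=(50, 2))
        expr = rng.random((50, 4))
        rep = spatial_cross_correlation(pts, -expr, pts, expr,
                                        bandwidth=1.0)
        assert all(v["score"] < 0 for v in rep.breakdown.values())

    def test_matches_unfiltered_double_loop_oracle(self, rng):
        nt, ns, G = 40, 50, 3
        tc = rng.uniform(0, 6, size=(nt, 2))
        sc = rng.uniform(0, 6, size=(ns, 2))
        te = rng.random((nt, G))
        se = rng.random((ns, G))
        b = 10.0  # 4b exceeds the domain diameter → no pair dropped
        rep = spatial_cross_correlation(sc, se, tc, te, bandwidth=b)
        for g in range(G):
            zt = (te[:, g] - te[:, g].mean()) / te[:, g].std()
            zs = (se[:, g] - se[:, g].mean()) / se[:, g].std()
            num = den = 0.0
            for i in range(nt):
                for j in range(ns):
                    w = np.exp(-((tc[i] - sc[j]) ** 2).sum() / (2 * b * b))
                    num += w * zt[i] * zs[j]
                    den += w
            assert rep.breakdown[g]["score"] == pytest.approx(num / den,
                                                              abs=1e-10)

    def test_zero_variance_gene_flagged(self, rng):
        pts = rng.uniform(0, 5, size=(20, 2))
        expr = rng.random((20, 2))
        expr[:, 0] = 3.0
        rep = spatial_cross_correlation(pts, expr, pts, expr, bandwidth=1.0)
        assert rep.breakdown[0]["zero_variance"]
        assert rep.breakdown[0]["score"] == 0.0


class TestPseudoSpotCosine:
    def test_identical_slices_all_ones(self, rng):
        pts = rng.uniform(0, 100, size=(80, 2))
        expr = rng.random((80, 5))
        rep = pseudo_spot_cosine(pts, expr, pts, expr, bin_size=30.0)
        assert rep.value == pytest.approx(1.0)

    def test_disjoint_gene_support_zero(self):
        pts = np.array([[5.0, 5.0], [6.0, 6.0]])
        src = np.array([[1.0, 0.0], [2.0, 0.0]])
        tgt = np.array([[0.0, 1.0], [0.0, 3.0]])
        rep = pseudo_spot_cosine(pts, src, pts, tgt, bin_size=30.0)
        assert rep.value == 0.0

    def test_hand_built_two_bins(self):
        # bin A: src (1,0), tgt (1,1); bin B: src (0,2), tgt (2,2)
        src_pts = np.array([[5.0, 5.0], [45.0, 5.0]])
        tgt_pts = np.array([[6.0, 6.0], [44.0, 4.0]])
        src_e = np.array([[1.0, 0.0], [0.0, 2.0]])
        tgt_e = np.array([[1.0, 1.0], [2.0, 2.0]])
        rep = pseudo_spot_cosine(src_pts, src_e, tgt_pts, tgt_e,
                                 bin_size=30.0)
        expect = np.mean([1 / np.sqrt(2), 2 / (2 * np.sqrt(2))])
        assert rep.value == pytest.approx(expect, abs=1e-12)

    def test_no_shared_bins_rejected(self):
        with pytest.raises(ValueError, match="co-occupied"):
            pseudo_spot_cosine(np.array([[0.0, 0]]), np.array([[1.0]]),
                               np.array([[500.0, 500]]), np.array([[1.0]]),
                               bin_size=10.0)

    def test_per_gene_profile_mode(self, rng):
        pts = rng.uniform(0, 90, size=(60, 2))
        expr = rng.random((60, 4))
        rep = pseudo_spot_cosine(pts, expr, pts, expr, bin_size=30.0, gene=1)
        assert -1.0 <= rep.value <= 1.0


class TestLandmarkMae:
    def test_identical_sets_zero(self, rng):
        pts = rng.random((6, 2))
        assert landmark_mae(LandmarkSet(pts, pts)).value == 0.0

    def test_distances_three_and_four(self):
        tgt = np.array([[0.0, 0], [0.0, 0]])
        src = np.array([[3.0, 0], [0.0, 4]])
        assert landmark_mae(LandmarkSet(tgt, src)).value == 3.5

    def test_unit_offset(self, rng):
        pts = rng.random((10, 2))
        lm = LandmarkSet(pts, pts + [1.0, 0.0])
        assert landmark_mae(lm).value == pytest.approx(1.0)

    def test_per_axis_variant(self):
        tgt = np.array([[0.0, 0]])
        src = np.array([[3.0, 4.0]])
        rep = landmark_mae(LandmarkSet(tgt, src), per_axis=True)
        assert rep.value == 3.5  # (|3|+|4|)/2
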