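"""Alignment quality metrics.

Five complementary measures: mutual-nearest-neighbour label consistency
(structural correspondence when anatomical annotations exist), joint-GMM
ARI/NMI (biological coherence of pooled clusterings), Gaussian-weighted
spatial cross-correlation (preservation of continuous expression gradients),
pseudo-spot cosine similarity (local molecular agreement for noisy
single-cell data) and landmark mean absolute error (geometry only; landmarks
are never used during optimization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.mixture import GaussianMixture

from .io_formats import LandmarkSet

__all__ = [
    "MetricReport",
    "label_consistency_accuracy",
    "gmm_cluster_scores",
    "spatial_cross_correlation",
    "pseudo_spot_cosine",
    "landmark_mae",
]


@dataclass
class MetricReport:
    name: str
    value: float
    breakdown: Optional[dict] = None
    params: dict = field(default_factory=dict)


def mutual_nearest_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross-set mutual nearest-neighbour index pairs (i in a, j in b).

    Nearest-neighbour ties are broken by the smallest point index so the
    pair set is deterministic.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ta, tb = cKDTree(a), cKDTree(b)
    _, nb = tb.query(a, k=1)   # nearest b for each a
    _, na = ta.query(b, k=1)   # nearest a for each b
    pairs = [(i, nb[i]) for i in range(len(a)) if na[nb[i]] == i]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def label_consistency_accuracy(src_coords_aligned, src_labels,
                               tgt_coords, tgt_labels) -> MetricReport:
    """Fraction of cross-slice MNN pairs sharing the same anatomical label."""
    src_labels = np.asarray(src_labels)
    tgt_labels = np.asarray(tgt_labels)
    pairs = mutual_nearest_pairs(np.asarray(tgt_coords, float),
                                 np.asarray(src_coords_aligned, float))
    if pairs.shape[0] == 0:
        raise ValueError("no mutual nearest-neighbour pairs")
    same = tgt_labels[pairs[:, 0]] == src_labels[pairs[:, 1]]
    return MetricReport(
        "label_consistency_accuracy", float(same.mean()),
        breakdown={"n_pairs": int(pairs.shape[0])},
    )


def gmm_cluster_scores(src_coords_aligned, src_expr, tgt_coords, tgt_expr,
                       labels, K: Optional[int] = None, n_pcs: int = 10,
                       seed: int = 0) -> MetricReport:
    """ARI/NMI of a joint GMM on pooled spatial + expression features.

    Features are standardized coordinates concatenated with a standardized
    top-PC embedding of expression, pooled over both aligned slices; the
    K-component full-covariance GMM assignment is compared with the
    ground-truth labels. K defaults to the number of distinct labels.
    """
    labels = np.asarray(labels)
    coords = np.vstack([np.asarray(tgt_coords, float),
                        np.asarray(src_coords_aligned, float)])
    expr = np.vstack([np.asarray(tgt_expr, float),
                      np.asarray(src_expr, float)])
    n = coords.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must cover pooled target then source points")
    if K is None:
        K = len(np.unique(labels))
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError("K exceeds the number of points")

    def standardize(M):
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        return (M - M.mean(axis=0)) / sd

    k_pcs = min(n_pcs, expr.shape[1], n)
    emb = PCA(n_components=k_pcs, random_state=seed).fit_transform(
        standardize(expr))
    feats = np.hstack([standardize(coords), standardize(emb)])
    gm = GaussianMixture(n_components=K, covariance_type="full",
                         n_init=3, random_state=seed, reg_covar=1e-6)
    assign = gm.fit_predict(feats)
    ari = float(adjusted_rand_score(labels, assign))
    nmi = float(normalized_mutual_info_score(labels, assign))
    return MetricReport("gmm_cluster_scores", ari,
                        breakdown={"ARI": ari, "NMI": nmi},
                        params={"K": K, "n_pcs": k_pcs})


def spatial_cross_correlation(src_coords_aligned, src_expr, tgt_coords,
                              tgt_expr, genes: Optional[Sequence[int]] = None,
                              bandwidth: Optional[float] = None,
                              ) -> MetricReport:
    """Gaussian-kernel-weighted cross-correlation of expression gradients.

    Per gene g: C_g = Σ_{i∈tgt, j∈src} w_ij z_i z_j / Σ w_ij with
    w_ij = exp(−d_ij²/(2b²)), pairs beyond 4b dropped, and z the per-slice
    standardized expression. Bandwidth b defaults to the median
    nearest-neighbour spacing of the target slice.
    """
    tgt_coords = np.asarray(tgt_coords, float)
    src_coords = np.asarray(src_coords_aligned, float)
    tgt_expr = np.asarray(tgt_expr, float)
    src_expr = np.asarray(src_expr, float)
    if genes is None:
        genes = list(range(tgt_expr.shape[1]))
    if bandwidth is None:
        tree = cKDTree(tgt_coords)
        d, _ = tree.query(tgt_coords, k=2)
        bandwidth = float(np.median(d[:, 1]))
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")

    tt = cKDTree(tgt_coords)
    ts = cKDTree(src_coords)
    pairs = tt.query_ball_tree(ts, r=4.0 * bandwidth)
    ii = np.concatenate([[i] * len(js) for i, js in enumerate(pairs)]) \
        if any(pairs) else np.zeros(0, int)
    jj = np.concatenate([js for js in pairs if js]).astype(int) \
        if any(pairs) else np.zeros(0, int)
    if ii.size == 0:
        raise ValueError("no point pairs within 4×bandwidth")
    d2 = ((tgt_coords[ii] - src_coords[jj]) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * bandwidth ** 2))
    wsum = w.sum()

    def zscore(v):
        sd = v.std()
        return None if sd == 0 else (v - v.mean()) / sd

    per_gene = {}
    vals = []
    for g in genes:
        zt = zscore(tgt_expr[:, g])
        zs = zscore(src_expr[:, g])
        if zt is None or zs is None:
            per_gene[g] = {"score": 0.0, "zero_variance": True}
            vals.append(0.0)
            continue
        c = float((w * zt[ii] * zs[jj]).sum() / wsum)
        per_gene[g] = {"score": c, "zero_variance": False}
        vals.append(c)
    return MetricReport("spatial_cross_correlation", float(np.mean(vals)),
                        breakdown=per_gene,
                        params={"bandwidth": bandwidth})


def _bin_indices(coords: np.ndarray, origin: np.ndarray,
                 bin_size: float) -> np.ndarray:
    return np.floor((coords - origin) / bin_size).astype(int)


def pseudo_spot_cosine(src_coords_aligned, src_expr, tgt_coords, tgt_expr,
                       bin_size: float = 30.0,
                       gene: Optional[int] = None) -> MetricReport:
    """Cosine similarity of square-binned (pseudo-spot) expression.

    Both slices are binned on one lattice anchored at the joint bounding-box
    corner; for bins occupied on both sides the per-bin expression vectors
    are compared. With ``gene`` given, the score is instead the cosine
    between that gene's source bin profile and the target's total-expression
    bin profile across co-occupied bins.
    """
    if not bin_size > 0:
        raise ValueError("bin_size must be positive")
    src_coords = np.asarray(src_coords_aligned, float)
    tgt_coords = np.asarray(tgt_coords, float)
    src_expr = np.asarray(src_expr, float)
    tgt_expr = np.asarray(tgt_expr, float)
    origin = np.vstack([src_coords, tgt_coords]).min(axis=0)

    def binsum(coords, expr):
        idx = _bin_indices(coords, origin, bin_size)
        out = {}
        for k, (bx, by) in enumerate(map(tuple, idx)):
            out.setdefault((bx, by), np.zeros(expr.shape[1]))
            out[(bx, by)] += expr[k]
        return out

    sbins = binsum(src_coords, src_expr)
    tbins = binsum(tgt_coords, tgt_expr)
    shared = sorted(set(sbins) & set(tbins))
    if not shared:
        raise ValueError("no co-occupied pseudo-spot bins")

    def cosine(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return 0.0
        return float(u @ v / (nu * nv))

    if gene is not None:
        prof_s = np.array([sbins[b][gene] for b in shared])
        prof_t = np.array([tbins[b].sum() for b in shared])
        val = cosine(prof_s, prof_t)
        return MetricReport("pseudo_spot_cosine", val,
                            breakdown={"n_bins": len(shared)},
                            params={"bin_size": bin_size, "gene": gene})
    per_bin = {b: cosine(sbins[b], tbins[b]) for b in shared}
    return MetricReport("pseudo_spot_cosine",
                        float(np.mean(list(per_bin.values()))),
                        breakdown={"per_bin": per_bin,
                                   "n_bins": len(shared)},
                        params={"bin_size": bin_size})


def landmark_mae(lm: LandmarkSet, result=None, per_axis: bool = False,
                 ) -> MetricReport:
    """Mean distance between target landmarks and (aligned) source landmarks.

    With ``result`` given the source landmarks are first transferred into
    the target frame. The default reads |·| as the per-landmark Euclidean
    norm; ``per_axis`` switches to the mean of per-axis absolute errors.
    """
    if lm.n < 1:
        raise ValueError("need at least one landmark")
    src = lm.source_pts
    if result is not None:
        from .align_pipeline import transfer_points
        src, _ = transfer_points(result, src, "source_to_target")
    diff = lm.target_pts - src
    if per_axis:
        per = np.abs(diff).mean(axis=1)
    else:
        per = np.linalg.norm(diff, axis=1)
    return MetricReport("landmark_mae", float(per.mean()),
                        breakdown={"per_landmark": per.tolist()},
                        params={"per_axis": per_axis, "n": lm.n})
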