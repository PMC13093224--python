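"""Spatially informative gene selection.

Genes are ranked by how well their expression can be predicted from spatial
position alone: for each gene, a leave-self-out k-nearest-neighbour
regression predicts each point's expression as the unweighted mean of its k
nearest other points (Euclidean distance on coordinates only), and the
coefficient of determination R² scores the prediction. High-R² genes carry
strong spatial structure and serve as alignment signal channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io_formats import PointDataset

logger = logging.getLogger("gala")

__all__ = ["GeneRanking", "rank_genes", "select_informative"]

DEFAULT_K = 10
DEFAULT_TOP = 3  # top three informative genes suffice by default


@dataclass
class GeneRanking:
    """Genes ordered by descending R² (ties broken lexicographically)."""

    gene_names: list
    r2: np.ndarray
    k: int

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        if len(self.gene_names) != self.r2.shape[0]:
            raise ValueError("one score per gene required")


def knn_r2(coords: np.ndarray, expr: np.ndarray, k: int) -> np.ndarray:
    """Leave-self-out kNN-regression R² per gene (column of ``expr``).

    Zero-variance genes score 0 by convention.
    """
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need more points than neighbours: n={n}, k={k}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    # drop self from each neighbour row (self is at distance 0; if duplicate
    # coordinates put it elsewhere, remove the first occurrence of i)
    neigh = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k] if (row == i).any() else row[:k]
        neigh[i] = row
    pred = expr[neigh].mean(axis=1)  # n×G
    ss_res = ((expr - pred) ** 2).sum(axis=0)
    ss_tot = ((expr - expr.mean(axis=0)) ** 2).sum(axis=0)
    r2 = np.zeros(expr.shape[1])
    nz = ss_tot > 0
    r2[nz] = 1.0 - ss_res[nz] / ss_tot[nz]
    return r2


def rank_genes(ds: PointDataset, k: int = DEFAULT_K) -> GeneRanking:
    """Rank all genes of ``ds`` by spatial predictability (kNN R²)."""
    r2 = knn_r2(ds.coords, ds.expr, k)
    order = sorted(range(len(ds.gene_names)),
                   key=lambda i: (-r2[i], ds.gene_names[i]))
    return GeneRanking([ds.gene_names[i] for i in order], r2[order], k)


def select_informative(ranking: GeneRanking, p: int = DEFAULT_TOP) -> list:
    """Take the top-``p`` gene names; warns and returns all if p exceeds G."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if not ranking.gene_names:
        raise ValueError("empty ranking")
    if p > len(ranking.gene_names):
        logger.warning(
            "requested %d genes but only %d ranked; using all",
            p, len(ranking.gene_names),
        )
        return list(ranking.gene_names)
    return list(ranking.gene_names[:p])


def shared_informative(ranking: GeneRanking, p: int, target_genes) -> list:
    """Top-``p`` ranked genes that also exist in the target dataset.

    Genes absent from the target are dropped with a warning and replaced by
    the next-ranked shared gene (channel-to-channel comparison requires the
    gene on both sides).
    """
    tset = set(target_genes)
    out = []
    for g in ranking.gene_names:
        if len(out) == p:
            break
        if g in tset:
            out.append(g)
        else:
            logger.warning("informative gene %r absent from target; skipped", g)
    if len(out) < p:
        logger.warning("only %d shared informative genes available", len(out))
    return out
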