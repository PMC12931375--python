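"""Normalization, embedding/batch-centering, clustering and marker detection.

The downstream spot statistics in this package depend only on cluster
labels and raw-count positivity, so the heavy single-cell machinery is
deliberately replaced by simple, fully specified stand-ins:

* normalization: log CP10K (``ln(1 + 1e4 * c / colsum)``) or clipped
  Pearson residuals of a fixed-dispersion negative-binomial null — a
  documented simplification of regularized-NB variance stabilization;
* batch correction: PCA on the top variable genes followed by per-batch
  mean-centering in PC space — a documented simplification of iterative
  mixture-based embedding correction;
* clustering: seeded k-means with fixed k instead of graph/resolution
  clustering.

Marker detection itself follows the standard one-vs-rest recipe exactly:
two-sided Wilcoxon rank-sum per gene (tie-corrected normal approximation,
exact enumeration for tiny groups), detection-fraction filter
min_pct = 0.25, log2 fold-change cutoff 0.25 on expm1 means, and
Benjamini–Hochberg adjustment over each cluster's tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .mia import bh_adjust

__all__ = [
    "Embedding",
    "normalize_counts",
    "reduce_and_correct",
    "cluster_spots",
    "find_markers",
    "wilcoxon_rank_sum",
]


@dataclass
class Embedding:
    """Spot × dimension embedding with per-spot batch labels."""

    coords: np.ndarray
    batches: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.batches = np.asarray(self.batches)
        if self.coords.shape[0] != self.batches.shape[0]:
            raise ValueError("batch labels misaligned with embedding rows")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite values")

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def _as_dense(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray(matrix.todense(), dtype=float)
    return np.asarray(matrix, dtype=float)


def normalize_counts(counts, method: str = "log_cp10k", theta: float = 100.0):
    """Normalize a genes × spots count matrix.

    ``log_cp10k``: natural log of 1 + counts scaled to 10,000 per spot.
    ``pearson_residual``: (c − mu) / sqrt(mu + mu²/theta) under a
    depth × gene-abundance product null, clipped at ±sqrt(n_spots).

    Spots with zero total counts are rejected (run QC first).
    """
    X = counts.tocsc() if sp.issparse(counts) else sp.csc_matrix(np.asarray(counts, float))
    if X.nnz and X.data.min() < 0:
        raise ValueError("counts must be nonnegative")
    colsum = np.asarray(X.sum(axis=0)).ravel()
    if np.any(colsum == 0):
        zero = np.flatnonzero(colsum == 0)
        raise ValueError(
            f"{len(zero)} spot(s) have zero total counts (first index {zero[0]}); "
            "apply qc_filter_spots before normalizing"
        )
    if method == "log_cp10k":
        out = X.astype(float).multiply(1e4 / colsum[None, :]).tocsr()
        out.data = np.log1p(out.data)
        return out
    if method == "pearson_residual":
        D = _as_dense(X)
        total = D.sum()
        mu = np.outer(D.sum(axis=1) / total, colsum)
        with np.errstate(invalid="ignore", divide="ignore"):
            resid = (D - mu) / np.sqrt(mu + mu**2 / theta)
        resid[~np.isfinite(resid)] = 0.0
        clip = np.sqrt(D.shape[1])
        return np.clip(resid, -clip, clip)
    raise ValueError(f"unknown normalization method {method!r}")


def _top_variable_genes(dense: np.ndarray, n_top: int) -> np.ndarray:
    var = dense.var(axis=1)
    n_top = min(n_top, dense.shape[0])
    return np.argsort(var)[::-1][:n_top]


def reduce_and_correct(
    normalized,
    batches,
    n_dims: int = 20,
    n_top_genes: int = 2000,
) -> Embedding:
    """PCA on the top variable genes, then per-batch mean-centering in PC
    space (each batch's rows shifted so batch means coincide with the global
    mean).  Deterministic: SVD signs fixed so each component's largest-
    magnitude loading is positive."""
    dense = _as_dense(normalized)  # genes × spots
    batches = np.asarray(batches)
    rows = _top_variable_genes(dense, n_top_genes)
    Xs = dense[rows].T  # spots × genes
    nz = Xs.std(axis=0) > 0
    if nz.sum() < n_dims:
        raise ValueError(
            f"n_dims={n_dims} exceeds the {int(nz.sum())} genes with nonzero variance"
        )
    Xs = Xs[:, nz]
    rank = min(Xs.shape[0] - 1, Xs.shape[1])
    if n_dims > rank:
        raise ValueError(f"n_dims={n_dims} exceeds data rank {rank}")
    pca = PCA(n_components=n_dims, svd_solver="full", random_state=0)
    coords = pca.fit_transform(Xs)
    # deterministic sign convention: largest-|loading| positive
    for j in range(n_dims):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    global_mean = coords.mean(axis=0)
    for b in np.unique(batches):
        rows_b = batches == b
        coords[rows_b] += global_mean - coords[rows_b].mean(axis=0)
    return Embedding(coords=coords, batches=batches)


def cluster_spots(embedding: Embedding, k: int, seed: int = 0) -> np.ndarray:
    """Seeded k-means over the embedding; labels 0..k−1."""
    n = embedding.coords.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(embedding.coords)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y, exact_max: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact enumeration (via the Mann–Whitney exact distribution) when both
    groups have ≤ ``exact_max`` observations and no ties; otherwise the
    tie-corrected normal approximation without continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0  # constant gene carries no rank information
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 <= exact_max and n2 <= exact_max and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.pvalue)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)


def _rank_sum_p_vectorized(dense: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Tie-corrected normal-approximation rank-sum p per gene (row) for
    one group vs the rest, vectorized over genes."""
    n = dense.shape[1]
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = stats.rankdata(dense, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction: sum of t^3 - t over tie groups, per gene
    tie_term = np.zeros(dense.shape[0])
    for g in range(dense.shape[0]):
        _, counts = np.unique(dense[g], return_counts=True)
        tie_term[g] = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u1 - mu) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~np.isfinite(z)] = 1.0  # constant gene
    return np.minimum(p, 1.0)


def find_markers(
    normalized,
    labels,
    min_pct: float = 0.25,
    min_log2fc: float = 0.25,
    alpha: float = 0.05,
    gene_symbols=None,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """One-vs-rest upregulated marker genes per cluster.

    Parameters mirror the standard single-cell recipe: a gene is tested for
    a cluster only when detected in ≥ ``min_pct`` of spots inside or outside
    it; log2 fold change uses expm1 means of the log-normalized values with
    pseudo-count ``eps``; p values are two-sided Wilcoxon rank-sum; BH
    adjustment runs over each cluster's tested genes; records are retained
    when ``log2fc ≥ min_log2fc`` (upregulated only) and ``p_adj ≤ alpha``.

    Returns a MarkerTable DataFrame with columns
    ``cluster_id, gene, log2fc, pct_in, pct_out, p, p_adj``, sorted within
    cluster by descending log2fc then gene symbol.
    """
    dense = _as_dense(normalized)
    labels = np.asarray(labels)
    n_genes, n_spots = dense.shape
    if labels.shape != (n_spots,):
        raise ValueError("labels misaligned with normalized matrix columns")
    if gene_symbols is None:
        gene_symbols = np.array([f"gene{i}" for i in range(n_genes)], dtype=object)
    else:
        gene_symbols = np.asarray(gene_symbols, dtype=object)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for one-vs-rest testing")

    expm1 = np.expm1(dense)
    detected = dense > 0
    records = []
    for cl in uniq:
        in_group = labels == cl
        n_in = int(in_group.sum())
        if n_in < 3:
            warnings.warn(f"cluster {cl!r} has {n_in} spots (<3); skipped", stacklevel=2)
            continue
        n_out = n_spots - n_in
        pct_in = detected[:, in_group].mean(axis=1)
        pct_out = detected[:, ~in_group].mean(axis=1)
        testable = np.maximum(pct_in, pct_out) >= min_pct
        if not np.any(testable):
            continue
        mean_in = expm1[:, in_group].mean(axis=1)
        mean_out = expm1[:, ~in_group].mean(axis=1)
        log2fc = np.log2((mean_in + eps) / (mean_out + eps))

        idx = np.flatnonzero(testable)
        if n_in <= 10 and n_out <= 10:
            p = np.array(
                [wilcoxon_rank_sum(dense[g, in_group], dense[g, ~in_group]) for g in idx]
            )
        else:
            p = _rank_sum_p_vectorized(dense[idx], in_group)
        p_adj = bh_adjust(p)
        for j, g in enumerate(idx):
            if log2fc[g] >= min_log2fc and p_adj[j] <= alpha:
                records.append(
                    {
                        "cluster_id": cl,
                        "gene": gene_symbols[g],
                        "log2fc": float(log2fc[g]),
                        "pct_in": float(pct_in[g]),
                        "pct_out": float(pct_out[g]),
                        "p": float(p[j]),
                        "p_adj": float(p_adj[j]),
                    }
                )
    table = pd.DataFrame(
        records,
        columns=["cluster_id", "gene", "log2fc", "pct_in", "pct_out", "p", "p_adj"],
    )
    if not table.empty:
        table = table.sort_values(
            ["cluster_id", "log2fc", "gene"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return table


def top_markers(table: pd.DataFrame, cluster_id, n: int = 300) -> list:
    """Top-``n`` markers of one cluster ranked by (log2fc desc, gene asc)."""
    sub = table.loc[table["cluster_id"] == cluster_id]
    sub = sub.sort_values(["log2fc", "gene"], ascending=[False, True])
    return list(sub["gene"].head(n))
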