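"""Expression preprocessing: filtering, normalization, clustering, isolation removal.

The per-cell count matrix is filtered (cells with >= 300 expressed genes,
then genes expressed in >= 1% of retained cells), log-normalized to a
10,000-count scale, reduced to its top principal components on scaled
highly variable genes, and clustered on a shared-nearest-neighbor graph
with Leiden community detection at resolution 1.2.  All stochastic steps
are driven by a single seed, and reclustering under a different seed only
re-runs the community detection on the stored graph — the property the
downstream significance test consumes.

Within each cluster, spatially isolated cells (mean distance to the 1%
nearest same-cluster cells more than six standard deviations above the
cluster mean) are removed before any spatial model is fitted, and genes
expressed in fewer than 1% of the cluster's cells can optionally be
dropped per cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import anndata as ad
import numpy as np
import scanpy as sc
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


class EmptyDatasetError(ValueError):
    """Raised when filtering removes every cell or every gene."""


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of the clustering pipeline (defaults follow common practice)."""

    min_genes_per_cell: int = 300
    min_cell_fraction_per_gene: float = 0.01
    scale_factor: float = 1e4
    n_top_genes: int = 2000
    n_pcs: int = 10
    n_neighbors: int = 20
    resolution: float = 1.2


def filter_cells_genes(
    adata: ad.AnnData,
    min_genes_per_cell: int = 300,
    min_cell_fraction_per_gene: float = 0.01,
) -> ad.AnnData:
    """Keep cells with enough expressed genes, then sufficiently common genes.

    Cells are retained when they have positive counts in at least
    ``min_genes_per_cell`` genes; genes are then retained when they have
    positive counts in at least ``min_cell_fraction_per_gene`` of the
    retained cells.  The cell filter runs first so the gene fraction is
    evaluated on the retained population.
    """
    adata = adata[np.asarray((adata.X > 0).sum(axis=1)).ravel() >= min_genes_per_cell].copy()
    if adata.n_obs == 0:
        raise EmptyDatasetError("no cells pass the expressed-gene threshold")
    n_cells_per_gene = np.asarray((adata.X > 0).sum(axis=0)).ravel()
    adata = adata[:, n_cells_per_gene >= min_cell_fraction_per_gene * adata.n_obs].copy()
    if adata.n_vars == 0:
        raise EmptyDatasetError("no genes pass the cell-fraction threshold")
    return adata


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalize and log-transform counts in place.

    Each entry becomes ``ln(1 + count / cell_total * scale_factor)``; the
    raw counts are kept in ``layers['counts']``.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise EmptyDatasetError("cells with zero total counts must be filtered first")
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=scale_factor)
    sc.pp.log1p(adata)
    return adata


def cluster_cells(
    adata: ad.AnnData,
    seed: int,
    config: ClusteringConfig | None = None,
    key_added: str = "cluster",
) -> np.ndarray:
    """Graph-based clustering of log-normalized cells, reproducible by seed.

    Selects highly variable genes, scales them, computes a PCA, builds a
    k-nearest-neighbor graph and runs Leiden community detection.  The
    graph is cached in ``adata`` so :func:`recluster` can redo only the
    community-detection step under a different seed.  Identical inputs and
    seed give identical labels.
    """
    config = config or ClusteringConfig()
    if adata.n_obs <= config.n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={config.n_neighbors} cells, got {adata.n_obs}"
        )
    sc.pp.highly_variable_genes(
        adata, n_top_genes=min(config.n_top_genes, adata.n_vars), flavor="seurat"
    )
    hvg_X = adata[:, adata.var["highly_variable"]].X
    if hasattr(hvg_X, "toarray"):
        hvg_X = hvg_X.toarray()
    scaled = sc.pp.scale(hvg_X, max_value=10, copy=True)
    n_comps = min(config.n_pcs, scaled.shape[1] - 1, adata.n_obs - 1)
    # PCA on the scaled HVG block via deterministic partial SVD
    import scipy.sparse.linalg as sla

    Xc = np.asarray(scaled, dtype=np.float64)
    Xc = Xc - Xc.mean(axis=0)
    u, s, _ = sla.svds(Xc, k=n_comps, random_state=0)
    order = np.argsort(s)[::-1]
    adata.obsm["X_pca"] = (u * s)[:, order]
    sc.pp.neighbors(
        adata, n_neighbors=config.n_neighbors, use_rep="X_pca", random_state=0
    )
    return recluster(adata, seed, resolution=config.resolution, key_added=key_added)


def recluster(
    adata: ad.AnnData,
    seed: int,
    resolution: float = 1.2,
    key_added: str = "cluster",
) -> np.ndarray:
    """Re-run Leiden on the cached neighbor graph under a new seed."""
    if "neighbors" not in adata.uns:
        raise ValueError("run cluster_cells first to build the neighbor graph")
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=int(seed),
        key_added=key_added,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    return adata.obs[key_added].to_numpy(int)


def isolation_neighbor_count(n: int) -> int:
    """Neighbor count for the isolation score: 1% of cells, clamped to [10, 50].

    The 1% is rounded up, and the result is additionally capped at ``n - 1``
    so tiny clusters remain well defined.
    """
    return min(min(50, max(10, math.ceil(0.01 * n))), n - 1)


def isolation_scores(coords: np.ndarray) -> np.ndarray:
    """Mean Euclidean distance from each cell to its k nearest cluster mates."""
    coords = np.asarray(coords, float)
    n = len(coords)
    k = isolation_neighbor_count(n)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    return dist[:, 1:].mean(axis=1)  # drop self-distance


def isolation_filter(coords: np.ndarray) -> np.ndarray:
    """Boolean mask of cells kept by the six-sigma isolation rule.

    A cell is removed when its isolation score exceeds the cluster mean
    score plus six sample standard deviations; with two cells nothing can
    be removed (sd over n-1 keeps both inside the band).
    """
    coords = np.asarray(coords, float)
    if len(coords) < 2:
        return np.ones(len(coords), dtype=bool)
    scores = isolation_scores(coords)
    cutoff = scores.mean() + 6.0 * scores.std(ddof=1)
    return scores <= cutoff


def per_cluster_gene_filter(
    cluster_X, min_cell_fraction: float = 0.01, enabled: bool = True
) -> np.ndarray:
    """Mask of genes expressed in at least ``min_cell_fraction`` of the cluster."""
    n_cells = cluster_X.shape[0]
    if not enabled:
        return np.ones(cluster_X.shape[1], dtype=bool)
    n_pos = np.asarray((cluster_X > 0).sum(axis=0)).ravel()
    return n_pos >= min_cell_fraction * n_cells


def preprocess(
    adata: ad.AnnData,
    seed: int,
    config: ClusteringConfig | None = None,
) -> ad.AnnData:
    """Full preprocessing: filter, normalize, cluster, flag isolated cells.

    Adds ``obs['cluster']`` (integer labels) and ``obs['spatially_isolated']``
    (per-cluster six-sigma flag); returns the filtered, normalized AnnData.
    """
    config = config or ClusteringConfig()
    adata = filter_cells_genes(
        adata, config.min_genes_per_cell, config.min_cell_fraction_per_gene
    )
    adata = log_normalize(adata, config.scale_factor)
    labels = cluster_cells(adata, seed, config)
    isolated = np.zeros(adata.n_obs, dtype=bool)
    if "spatial" in adata.obsm:
        coords = adata.obsm["spatial"]
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if len(idx) >= 2:
                isolated[idx] = ~isolation_filter(coords[idx])
    adata.obs["spatially_isolated"] = isolated
    n_iso = int(isolated.sum())
    if n_iso:
        logger.info("flagged %d spatially isolated cells", n_iso)
    return adata
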