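"""Spatial gene modules: k-means on standardized fitted surfaces, metagenes, enrichment.

Within a cluster, the fitted spatial surface of every significant SVG is
standardized across cells to zero mean and unit standard deviation, so
genes are grouped by the shape of their pattern rather than its scale.
The standardized surfaces are clustered with Euclidean k-means; the module
count is chosen from the within-SS/total-SS curve over ``k = 1..k_max`` as
the elbow — the point of maximum perpendicular distance from the chord
joining the curve's endpoints.  Each module is summarized by a metagene,
the per-cell mean of its members' standardized fitted values, and can be
tested for gene-set over-representation with one-sided hypergeometric
tests against a user-supplied GMT, BH-adjusted, kept at q <= 0.05 and
ordered by decreasing fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .significance import bh_fdr

logger = logging.getLogger(__name__)


def standardize_fits(fitted: np.ndarray, gene_names=None) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each gene's fitted surface to mean 0, sd 1 across cells.

    Genes with a flat fit (zero sd) carry no pattern and are excluded.
    Returns ``(standardized (m' x n), kept gene mask (m,))``.
    """
    fitted = np.atleast_2d(np.asarray(fitted, float))
    sd = fitted.std(axis=1, ddof=0)
    keep = sd > 0
    n_flat = int((~keep).sum())
    if n_flat:
        names = list(np.asarray(gene_names)[~keep]) if gene_names is not None else n_flat
        logger.info("excluding flat-fit genes from module analysis: %s", names)
    z = (fitted[keep] - fitted[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return z, keep


def _kmeans(Z: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)


def choose_module_count(Z: np.ndarray, k_max: int = 10, seed: int = 0) -> int:
    """Elbow of the within-SS/total-SS curve of k-means over ``k = 1..k_max``.

    The curve point with the maximum perpendicular distance to the straight
    line through the first and last points is taken as the elbow.  ``k_max``
    is lowered to the number of distinct genes when fewer are available.
    """
    Z = np.atleast_2d(Z)
    n_distinct = len(np.unique(Z, axis=0))
    k_max = min(k_max, n_distinct)
    if k_max <= 1:
        return 1
    ks = np.arange(1, k_max + 1)
    tss = ((Z - Z.mean(axis=0)) ** 2).sum()
    ratio = np.array([_kmeans(Z, int(k), seed).inertia_ / tss for k in ks])
    # perpendicular distance from each point to the endpoint chord
    p1 = np.array([ks[0], ratio[0]])
    p2 = np.array([ks[-1], ratio[-1]])
    chord = p2 - p1
    chord = chord / np.linalg.norm(chord)
    pts = np.column_stack([ks, ratio]) - p1
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0])
    return int(ks[np.argmax(dist)])


def kmeans_modules(Z: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Module label per gene from seeded Euclidean k-means (10 restarts)."""
    Z = np.atleast_2d(Z)
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, len(np.unique(Z, axis=0)))
    return _kmeans(Z, k, seed).labels_


def metagene(Z_module: np.ndarray) -> np.ndarray:
    """Per-cell unweighted mean of a module's standardized fitted values."""
    Z_module = np.atleast_2d(Z_module)
    if Z_module.shape[0] == 0:
        raise ValueError("metagene of an empty module")
    return Z_module.mean(axis=0)


def enrich_modules(
    module_genes: set[str],
    background_genes: set[str],
    gene_sets: dict[str, list[str]],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a module.

    For each term restricted to the background, the one-sided p-value for
    observing at least the overlap by chance is computed, BH-adjusted
    across terms; terms at q <= ``fdr_cutoff`` are returned sorted by
    decreasing fold change, where fold change = (overlap / module size) /
    (term size / background size).  Terms with no background member are
    excluded from testing.
    """
    module_genes = set(module_genes) & set(background_genes)
    N, n = len(background_genes), len(module_genes)
    if not gene_sets:
        logger.warning("empty gene-set table; enrichment skipped")
        return pd.DataFrame(columns=["term", "overlap", "term_size", "fold_change", "pvalue", "qvalue"])
    rows = []
    for term, genes in gene_sets.items():
        term_bg = set(genes) & set(background_genes)
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & module_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append((term, k, K, fold, p))
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "fold_change", "pvalue"])
    if table.empty:
        table["qvalue"] = []
        return table
    table["qvalue"] = bh_fdr(table["pvalue"].to_numpy())
    table = table[table["qvalue"] <= fdr_cutoff]
    return table.sort_values("fold_change", ascending=False).reset_index(drop=True)


@dataclass
class ModuleResult:
    """Gene modules of one cluster."""

    cluster: int
    k: int
    assignments: pd.DataFrame  # gene, module
    metagenes: np.ndarray  # k x n_cells
    enrichment: dict[int, pd.DataFrame] = field(default_factory=dict)


def build_modules(
    fitted: np.ndarray,
    gene_names,
    cluster: int,
    k: int | None = None,
    k_max: int = 10,
    seed: int = 0,
    gene_sets: dict[str, list[str]] | None = None,
    background_genes: set[str] | None = None,
) -> ModuleResult | None:
    """Standardize fits, pick k, cluster genes, and summarize each module.

    ``fitted`` is the (m genes x n cells) matrix of fitted surfaces for the
    cluster's significant SVGs.  Returns ``None`` when no gene carries a
    non-flat pattern.
    """
    gene_names = np.asarray(gene_names)
    Z, keep = standardize_fits(fitted, gene_names)
    if Z.shape[0] == 0:
        return None
    names = gene_names[keep]
    if k is None:
        k = choose_module_count(Z, k_max=k_max, seed=seed)
    labels = kmeans_modules(Z, k, seed=seed)
    k = int(labels.max()) + 1
    metas = np.vstack([metagene(Z[labels == m]) for m in range(k)])
    result = ModuleResult(
        cluster=cluster,
        k=k,
        assignments=pd.DataFrame({"gene": names, "cluster": cluster, "module": labels}),
        metagenes=metas,
    )
    if gene_sets:
        background = set(background_genes) if background_genes is not None else set(names)
        for m in range(k):
            result.enrichment[m] = enrich_modules(
                set(names[labels == m]), background, gene_sets
            )
    return result


def plot_modules(result: ModuleResult, coords: np.ndarray, out_prefix: str) -> list[str]:
    """Spatial scatter of each module's metagene; returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for m in range(result.k):
        fig, ax = plt.subplots(figsize=(4, 4))
        sca = ax.scatter(
            coords[:, 0], coords[:, 1], c=result.metagenes[m], s=4, cmap="viridis"
        )
        ax.invert_yaxis()
        ax.set_title(f"cluster {result.cluster} module {m} ({(result.assignments['module'] == m).sum()} genes)")
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        fig.colorbar(sca, ax=ax, label="metagene")
        path = f"{out_prefix}_cluster{result.cluster}_module{m}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
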