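"""Permutation significance for cell-type-specific SVGs with clustering uncertainty.

Cluster labels are themselves estimates, so a permutation null that holds
the observed clusters fixed understates the variability of the test
statistic.  The procedure here re-runs the community-detection step under
seeds ``1..n_seeds`` (default 1,000) on the cached neighbor graph, matches
every original cluster to the reassigned cluster with the highest Jaccard
index, and keeps the ``n_keep`` (default 100) best-matching reassigned
clusters across seeds.  For each kept match, the spatial locations of its
cells are permuted uniformly at random while expression stays fixed, the
spline model is refitted, and the per-gene F statistic is recorded — one
null statistic per match, ``n_keep`` per gene.  A Gamma distribution is
fitted to the null statistics by maximum likelihood so p-values keep
resolution beyond 1/n_keep in the far tail, and Benjamini-Hochberg FDR
control is applied within each cluster (optionally globally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import preprocessing, spline

logger = logging.getLogger(__name__)

EPS = np.finfo(float).eps


@dataclass(frozen=True)
class SignificanceConfig:
    """Permutation-test knobs; defaults are the full-scale procedure."""

    n_seeds: int = 1000
    n_keep: int = 100
    n_internal_knots: int = 3
    fdr_cutoff: float = 0.05
    resolution: float = 1.2
    global_fdr: bool = False
    min_null: int = 10  # below this, or on degenerate nulls, use the empirical fallback


def jaccard(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union


@dataclass(frozen=True)
class ClusterMatch:
    """Best-Jaccard reassigned cluster for one original cluster and seed."""

    cluster: int
    seed: int
    jaccard: float
    cells: np.ndarray  # integer positions into the AnnData


def recluster_ensemble(
    adata: ad.AnnData,
    labels: np.ndarray,
    n_seeds: int = 1000,
    n_keep: int = 100,
    resolution: float = 1.2,
) -> dict[int, list[ClusterMatch]]:
    """Reassigned-cluster ensemble matched to the original clusters.

    For each seed in ``1..n_seeds`` the community detection is re-run on
    the cached neighbor graph.  Per original cluster the argmax-Jaccard
    reassigned cluster is retained for that seed (ties toward the smaller
    reassigned label), and across seeds the ``n_keep`` matches with the
    highest Jaccard are kept (ties toward the smaller seed).  Identical
    matched sets from different seeds are all kept; each later receives an
    independent location permutation.
    """
    if n_keep > n_seeds:
        raise ValueError("n_keep cannot exceed n_seeds")
    labels = np.asarray(labels)
    originals = {c: set(np.flatnonzero(labels == c)) for c in np.unique(labels)}
    matches: dict[int, list[ClusterMatch]] = {c: [] for c in originals}
    for seed in range(1, n_seeds + 1):
        try:
            new = preprocessing.recluster(adata, seed, resolution=resolution, key_added="_ens")
        except Exception:  # pragma: no cover - defensive: skip failing seeds
            logger.warning("reclustering failed at seed %d; skipped", seed)
            continue
        new_sets = {c: set(np.flatnonzero(new == c)) for c in np.unique(new)}
        for c, cells in originals.items():
            best_label, best_j = None, -1.0
            for nc in sorted(new_sets):
                j = jaccard(cells, new_sets[nc])
                if j > best_j:
                    best_label, best_j = nc, j
            matches[c].append(
                ClusterMatch(
                    cluster=int(c),
                    seed=seed,
                    jaccard=best_j,
                    cells=np.fromiter(sorted(new_sets[best_label]), dtype=int),
                )
            )
    for c in matches:
        matches[c].sort(key=lambda m: (-m.jaccard, m.seed))
        if len(matches[c]) < n_keep:
            logger.warning(
                "cluster %s: only %d successful matches (< n_keep=%d); using all",
                c, len(matches[c]), n_keep,
            )
        matches[c] = matches[c][:n_keep]
    return matches


def null_statistics(
    Y_all: np.ndarray,
    coords_all: np.ndarray,
    matches: list[ClusterMatch],
    global_seed: int,
    cluster_id: int,
    n_internal_knots: int = 3,
) -> np.ndarray:
    """Per-gene null F statistics, one per matched reassigned cluster.

    ``Y_all``/``coords_all`` cover all retained cells (genes restricted to
    the original cluster's gene list).  For each match, the coordinate rows
    of the matched cells are permuted uniformly at random, the design is
    rebuilt on the permuted coordinates, and every gene's F is computed.
    The permutation RNG is derived from ``(global_seed, cluster_id,
    replicate index)`` so reruns are reproducible.  Matches too small for
    the spline design are skipped with a warning.

    Returns an ``(m, n_used)`` array.
    """
    cols = []
    for rep, match in enumerate(matches):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(global_seed), int(cluster_id), rep])
        )
        cells = match.cells
        coords = coords_all[cells][rng.permutation(len(cells))]
        try:
            design = spline.build_design(coords, n_internal_knots)
        except (spline.InsufficientCellsError, spline.DegenerateGeometryError) as err:
            logger.warning("cluster %d replicate %d skipped: %s", cluster_id, rep, err)
            continue
        cols.append(spline.fit_genes(Y_all[:, cells], design)["f"])
    if not cols:
        return np.empty((Y_all.shape[0], 0))
    return np.column_stack(cols)


def gamma_pvalue(null_f: np.ndarray, observed_f: float, min_null: int = 10) -> tuple[float, bool]:
    """Upper-tail p-value from a Gamma fitted to the permutation nulls.

    The Gamma (shape/scale, location fixed at zero) is fitted by maximum
    likelihood with a method-of-moments start.  When the observed statistic
    is non-finite (an exact fit) the p-value is the machine-epsilon floor;
    when the nulls are too few, degenerate, or the fit fails, the empirical
    ``(#{null >= observed} + 1) / (n + 1)`` estimate is used instead.

    Returns ``(p, fallback_used)``.
    """
    null_f = np.asarray(null_f, float)
    null_f = null_f[np.isfinite(null_f)]
    if not np.isfinite(observed_f):
        return EPS, False
    if observed_f <= 0:
        return 1.0, False
    degenerate = len(null_f) < min_null or null_f.std() == 0 or np.all(null_f <= 0)
    if not degenerate:
        try:
            positive = np.maximum(null_f, EPS)
            mean, var = positive.mean(), positive.var()
            a0 = mean**2 / var if var > 0 else 1.0
            shape, _, scale = stats.gamma.fit(
                positive, a0, floc=0.0, scale=mean / a0
            )
            if np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0:
                p = float(stats.gamma.sf(observed_f, shape, loc=0.0, scale=scale))
                return max(p, EPS), False
        except Exception:  # pragma: no cover - rare optimizer failures
            pass
    p = (np.sum(null_f >= observed_f) + 1.0) / (len(null_f) + 1.0)
    return float(min(p, 1.0)), True


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    pvalues = np.asarray(pvalues, float)
    if len(pvalues) == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def run_significance(
    adata: ad.AnnData,
    global_seed: int,
    config: SignificanceConfig | None = None,
    cluster_key: str = "cluster",
    gene_filter_enabled: bool = True,
) -> pd.DataFrame:
    """Run the full SVG significance procedure on a preprocessed dataset.

    Expects ``adata`` from :func:`cellsvg.preprocessing.preprocess`
    (log-normalized ``X``, ``obs[cluster_key]``, ``obs['spatially_isolated']``,
    ``obsm['spatial']`` and a cached neighbor graph).  Returns a tidy frame
    with one row per (cluster, gene): F statistic, Gamma-tail p, BH q,
    number of null statistics used and the fallback flag.
    """
    config = config or SignificanceConfig()
    labels = adata.obs[cluster_key].to_numpy(int)
    isolated = adata.obs.get(
        "spatially_isolated", pd.Series(False, index=adata.obs_names)
    ).to_numpy(bool)
    coords_all = np.asarray(adata.obsm["spatial"], float)
    X_all = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)

    ensemble = recluster_ensemble(
        adata, labels, n_seeds=config.n_seeds, n_keep=config.n_keep,
        resolution=config.resolution,
    )

    frames = []
    for c in np.unique(labels):
        members = np.flatnonzero((labels == c) & ~isolated)
        if len(members) < 2:
            logger.warning("cluster %d: too few cells after isolation filter; skipped", c)
            continue
        gene_mask = preprocessing.per_cluster_gene_filter(
            adata.layers["counts"][members] if "counts" in adata.layers else X_all[members],
            enabled=gene_filter_enabled,
        )
        genes = adata.var_names[gene_mask]
        Y = X_all[np.ix_(members, gene_mask)].T  # m x n
        try:
            design = spline.build_design(coords_all[members], config.n_internal_knots)
        except (spline.InsufficientCellsError, spline.DegenerateGeometryError) as err:
            logger.warning("cluster %d skipped: %s", c, err)
            continue
        observed = spline.fit_genes(Y, design)["f"]

        null_f = null_statistics(
            X_all[:, :].T[gene_mask],  # genes x all cells
            coords_all,
            ensemble.get(int(c), []),
            global_seed,
            int(c),
            config.n_internal_knots,
        )
        pvals = np.empty(len(genes))
        fallback = np.empty(len(genes), dtype=bool)
        for i in range(len(genes)):
            pvals[i], fallback[i] = gamma_pvalue(null_f[i], observed[i], config.min_null)
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "cluster": int(c),
                    "f_statistic": observed,
                    "pvalue": pvals,
                    "n_null_used": null_f.shape[1],
                    "gamma_fallback": fallback,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["gene", "cluster", "f_statistic", "pvalue", "qvalue",
                     "n_null_used", "gamma_fallback", "significant"]
        )
    results = pd.concat(frames, ignore_index=True)
    if config.global_fdr:
        results["qvalue"] = bh_fdr(results["pvalue"].to_numpy())
    else:
        results["qvalue"] = (
            results.groupby("cluster")["pvalue"].transform(lambda p: bh_fdr(p.to_numpy()))
        )
    results["significant"] = results["qvalue"] <= config.fdr_cutoff
    return results
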