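"""Stage orchestration: each stage reads the previous stage's on-disk artifacts.

Stages (also exposed as CLI subcommands in :mod:`cellsvg.cli`):

- ``aggregate``: bin counts + nucleus GeoJSON -> per-cell count matrix;
- ``preprocess``: per-cell counts -> normalized matrix, cluster labels and
  isolation flags;
- ``svg``: per-cell counts -> per-cluster SVG result tables (the stage
  reruns the seeded preprocessing internally so the reclustering ensemble
  can reuse the neighbor graph);
- ``modules``: SVG results + per-cell counts -> gene modules, metagenes
  and optional enrichment/plots.

Every stage writes a ``manifest.json`` recording the configuration, seed
and package version, and identical configurations produce identical output
tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as csio
from . import modules as csmodules
from . import preprocessing, significance, simulate, spline
from .geometry import ExpansionConfig, bins_to_cells
from .preprocessing import ClusteringConfig
from .significance import SignificanceConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs in one flat, serializable record."""

    seed: int = 0
    expansion: ExpansionConfig = field(default_factory=ExpansionConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    per_cluster_gene_filter: bool = True
    module_k_max: int = 10

    def reduced(self) -> "PipelineConfig":
        """Down-scaled profile: 50 reclustering seeds, 20 kept matches."""
        from dataclasses import replace

        return replace(
            self, significance=replace(self.significance, n_seeds=50, n_keep=20)
        )


def simulation_study_config(seed: int = 0, n_genes: int = 200,
                            reduced: bool = True) -> PipelineConfig:
    """Analysis configuration matched to :func:`cellsvg.simulate.study_conditions`.

    Synthetic datasets carry far fewer genes than a transcriptome, so the
    expressed-gene cell filter is scaled to a quarter of the gene panel,
    and the clustering resolution is 0.1 — the coarse setting used when
    clusters should align with a handful of planted types.  ``reduced``
    selects the down-scaled significance profile (50 seeds, 20 kept).
    """
    config = PipelineConfig(
        seed=seed,
        clustering=ClusteringConfig(
            min_genes_per_cell=min(300, max(1, n_genes // 4)), resolution=0.1
        ),
        significance=SignificanceConfig(resolution=0.1),
    )
    return config.reduced() if reduced else config


def _write_manifest(out: Path, stage: str, config: PipelineConfig, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "config": {
            "seed": config.seed,
            "expansion": asdict(config.expansion),
            "clustering": asdict(config.clustering),
            "significance": asdict(config.significance),
            "per_cluster_gene_filter": config.per_cluster_gene_filter,
            "module_k_max": config.module_k_max,
        },
    }
    manifest.update(extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_aggregate(bins_dir: str | Path, nuclei_path: str | Path, out_dir: str | Path,
                  config: PipelineConfig | None = None) -> Path:
    """Bin-to-cell stage: read bin counts + GeoJSON, write the cell matrix."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = csio.read_bin_dataset(bins_dir)
    nuclei = csio.read_nuclei_geojson(nuclei_path)
    adata, assignment, abnormal = bins_to_cells(
        dataset.counts, dataset.genes, dataset.barcodes, dataset.positions,
        nuclei, config.expansion,
    )
    csio.write_cell_dataset(adata, out)
    assignment.to_csv(out / "assignment.tsv", sep="\t", index=False)
    _write_manifest(out, "aggregate", config, {
        "n_nuclei_input": len(nuclei),
        "n_cells_output": int(adata.n_obs),
        "n_abnormal_cells": len(abnormal),
        "n_squares_assigned": int(len(assignment)),
    })
    logger.info("aggregate stage finished in %.1f s", time.perf_counter() - t0)
    return out


def _load_and_preprocess(cells_dir: str | Path, config: PipelineConfig):
    adata = csio.read_cell_dataset(cells_dir)
    if "spatial" not in adata.obsm:
        raise ValueError("cells.tsv must provide x_um/y_um coordinates")
    return preprocessing.preprocess(adata, config.seed, config.clustering)


def run_preprocess(cells_dir: str | Path, out_dir: str | Path,
                   config: PipelineConfig | None = None) -> Path:
    """Filter, normalize, cluster; write cell metadata and normalized matrix."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adata = _load_and_preprocess(cells_dir, config)
    meta = adata.obs.copy()
    meta["x_um"] = adata.obsm["spatial"][:, 0]
    meta["y_um"] = adata.obsm["spatial"][:, 1]
    meta.to_csv(out / "cells.tsv", sep="\t")
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(out / "lognorm.mtx", sparse.coo_matrix(adata.X))
    pd.Series(adata.var_names).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    _write_manifest(out, "preprocess", config, {
        "n_cells": int(adata.n_obs), "n_genes": int(adata.n_vars),
        "n_clusters": int(adata.obs["cluster"].nunique()),
        "n_isolated": int(adata.obs["spatially_isolated"].sum()),
    })
    logger.info("preprocess stage finished in %.1f s", time.perf_counter() - t0)
    return out


def run_svg(cells_dir: str | Path, out_dir: str | Path,
            config: PipelineConfig | None = None) -> pd.DataFrame:
    """Full SVG testing stage; writes per-cluster result TSVs."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adata = _load_and_preprocess(cells_dir, config)
    results = significance.run_significance(
        adata, config.seed, config.significance,
        gene_filter_enabled=config.per_cluster_gene_filter,
    )
    results.to_csv(out / "svg_results.tsv", sep="\t", index=False)
    for c, grp in results.groupby("cluster"):
        grp.to_csv(out / f"svg_results_cluster{c}.tsv", sep="\t", index=False)
    _write_manifest(out, "svg", config, {
        "n_tests": int(len(results)),
        "n_significant": int(results["significant"].sum()) if len(results) else 0,
    })
    logger.info("svg stage finished in %.1f s", time.perf_counter() - t0)
    return results


def cluster_fits(adata, config: PipelineConfig, genes: list[str], cluster: int):
    """Fitted spatial surfaces of the given genes in one cluster.

    Returns ``(fitted (m x n_cells), member index, coords)``; used by the
    modules stage, which needs the observed fits of the significant SVGs.
    """
    labels = adata.obs["cluster"].to_numpy(int)
    isolated = adata.obs["spatially_isolated"].to_numpy(bool)
    members = np.flatnonzero((labels == cluster) & ~isolated)
    coords = np.asarray(adata.obsm["spatial"], float)[members]
    gene_idx = [adata.var_names.get_loc(g) for g in genes]
    X = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)
    Y = X[np.ix_(members, gene_idx)].T
    design = spline.build_design(coords, config.significance.n_internal_knots)
    return spline.fit_genes(Y, design)["fitted"], members, coords


def run_modules(cells_dir: str | Path, svg_dir: str | Path, out_dir: str | Path,
                config: PipelineConfig | None = None,
                gmt_path: str | Path | None = None,
                plots: bool = False) -> pd.DataFrame:
    """Module stage: group each cluster's significant SVGs into spatial modules."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_path = Path(svg_dir) / "svg_results.tsv"
    if not results_path.exists():
        raise FileNotFoundError(f"missing SVG results table {results_path}")
    results = pd.read_csv(results_path, sep="\t")
    gene_sets = csio.read_gmt(gmt_path) if gmt_path else None
    adata = _load_and_preprocess(cells_dir, config)

    assignments, n_plots = [], 0
    for c, grp in results.groupby("cluster"):
        sig = grp[grp["significant"]]
        if sig.empty:
            logger.warning("cluster %s has no significant SVGs; skipping modules", c)
            continue
        fitted, members, coords = cluster_fits(adata, config, sig["gene"].tolist(), int(c))
        result = csmodules.build_modules(
            fitted, sig["gene"].to_numpy(), int(c),
            k_max=config.module_k_max, seed=config.seed,
            gene_sets=gene_sets, background_genes=set(grp["gene"]),
        )
        if result is None:
            continue
        assignments.append(result.assignments)
        pd.DataFrame(
            result.metagenes.T,
            index=adata.obs_names[members],
            columns=[f"module_{m}" for m in range(result.k)],
        ).to_csv(out / f"metagenes_cluster{c}.tsv", sep="\t")
        for m, table in result.enrichment.items():
            table.to_csv(out / f"enrichment_cluster{c}_module{m}.tsv", sep="\t", index=False)
        if plots:
            n_plots += len(csmodules.plot_modules(result, coords, str(out / "module")))
    table = (
        pd.concat(assignments, ignore_index=True)
        if assignments
        else pd.DataFrame(columns=["gene", "cluster", "module"])
    )
    table.to_csv(out / "modules.tsv", sep="\t", index=False)
    _write_manifest(out, "modules", config, {
        "n_module_genes": int(len(table)), "n_plots": n_plots,
    })
    logger.info("modules stage finished in %.1f s", time.perf_counter() - t0)
    return table


def run_simulate(out_dir: str | Path, sim_config: simulate.SimulationConfig,
                 mode: str = "bin", null: bool = False) -> Path:
    """Write a synthetic dataset in the exact input formats of the pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if mode == "bin":
        nuclei, types, counts, positions, truth, cell_totals = simulate.simulate_bin_dataset(sim_config)
        csio.write_bin_dataset(
            csio.BinDataset(
                counts=counts,
                genes=[f"gene_{i}" for i in range(sim_config.n_genes)],
                barcodes=positions["barcode"].tolist(),
                positions=positions,
            ),
            out,
        )
        csio.write_nuclei_geojson(nuclei, out / "nuclei.geojson")
        pd.DataFrame({
            "nucleus_id": [n.nucleus_id for n in nuclei],
            "true_type": types,
            "true_total": cell_totals.sum(axis=1),
        }).to_csv(out / "truth_cells.tsv", sep="\t", index=False)
        truth.flags_frame([f"gene_{i}" for i in range(sim_config.n_genes)]).to_csv(
            out / "truth_genes.tsv", sep="\t", index=False
        )
    elif mode == "cell":
        adata = simulate.simulate_cell_dataset(sim_config)
        if null:
            adata = simulate.make_null_dataset(adata, sim_config.seed + 1)
        csio.write_cell_dataset(adata, out)
        flags = adata.uns["svg_flags"]
        rows = [
            (g, t, bool(flags[i, t]))
            for i, g in enumerate(adata.var_names)
            for t in range(flags.shape[1])
        ]
        pd.DataFrame(rows, columns=["gene", "type", "is_svg"]).to_csv(
            out / "truth_genes.tsv", sep="\t", index=False
        )
    else:
        raise ValueError("mode must be 'bin' or 'cell'")
    (out / "sim_manifest.json").write_text(
        json.dumps({"mode": mode, "null": null, "config": asdict(sim_config)}, indent=2, default=str)
    )
    return out
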