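"""Readers and writers for the on-disk formats used by the pipeline.

Bin-level inputs follow the Space Ranger layout: a MatrixMarket counts
matrix (genes x squares), a features TSV, a barcodes TSV and a square
position table (CSV or Parquet with columns ``barcode, array_row,
array_col, x_um, y_um``).  Nucleus segmentations are a GeoJSON
FeatureCollection of Polygon features with an ``id`` property.  Cell-level
artifacts are written as MTX plus TSV sidecars so every output stays
plain-text and platform-neutral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .geometry import NucleusPolygon


@dataclass
class BinDataset:
    """Bin-level counts with sidecars: genes x squares."""

    counts: sparse.spmatrix
    genes: list[str]
    barcodes: list[str]
    positions: pd.DataFrame


def read_bin_dataset(directory: str | Path) -> BinDataset:
    d = Path(directory)
    pos_csv, pos_parquet = d / "positions.csv", d / "positions.parquet"
    if not pos_csv.exists() and not pos_parquet.exists():
        raise FileNotFoundError(f"no positions.csv or positions.parquet in {d}")
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing {name} in {d}")
    counts = sparse.csr_matrix(spio.mmread(d / "matrix.mtx"))
    genes = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    positions = pd.read_csv(pos_csv) if pos_csv.exists() else pd.read_parquet(pos_parquet)
    positions["barcode"] = positions["barcode"].astype(str)
    return BinDataset(counts=counts, genes=genes, barcodes=barcodes, positions=positions)


def write_bin_dataset(dataset: BinDataset, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(d / "matrix.mtx", sparse.coo_matrix(dataset.counts))
    pd.Series(dataset.genes).to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(dataset.barcodes).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    dataset.positions.to_csv(d / "positions.csv", index=False)


def read_nuclei_geojson(path: str | Path, scale: float = 1.0) -> list[NucleusPolygon]:
    """Load nucleus polygons from a GeoJSON FeatureCollection.

    Each feature must be a Polygon with an integer ``id`` property;
    ``scale`` converts the stored coordinates to µm (1.0 when the file is
    already in µm).
    """
    with open(path) as fh:
        collection = json.load(fh)
    nuclei = []
    for feature in collection["features"]:
        geom = feature["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError(f"unsupported geometry type {geom['type']!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=float) * scale
        nuclei.append(NucleusPolygon(nucleus_id=int(feature["properties"]["id"]), contour=ring))
    return nuclei


def write_nuclei_geojson(nuclei: list[NucleusPolygon], path: str | Path) -> None:
    features = []
    for n in nuclei:
        ring = np.vstack([n.contour, n.contour[:1]]).tolist()
        features.append(
            {
                "type": "Feature",
                "properties": {"id": int(n.nucleus_id)},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_cell_dataset(adata: ad.AnnData, directory: str | Path) -> None:
    """Write a cells x genes AnnData as MTX counts plus TSV sidecars."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = adata.X
    spio.mmwrite(d / "matrix.mtx", sparse.coo_matrix(X))
    pd.Series(adata.var_names).to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    obs = adata.obs.copy()
    if "spatial" in adata.obsm:
        obs["x_um"] = adata.obsm["spatial"][:, 0]
        obs["y_um"] = adata.obsm["spatial"][:, 1]
    obs.to_csv(d / "cells.tsv", sep="\t")


def read_cell_dataset(directory: str | Path) -> ad.AnnData:
    """Read a cell-level dataset written by :func:`write_cell_dataset`.

    This is also the entry point for non-binned platforms: any cells x
    genes MTX plus a ``cells.tsv`` with ``x_um``/``y_um`` columns works.
    """
    d = Path(directory)
    X = sparse.csr_matrix(spio.mmread(d / "matrix.mtx"))
    genes = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    obs = pd.read_csv(d / "cells.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    if {"x_um", "y_um"} <= set(obs.columns):
        adata.obsm["spatial"] = obs[["x_um", "y_um"]].to_numpy(float)
    return adata


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into ``{term: [genes]}``."""
    gene_sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            gene_sets[parts[0]] = [g for g in parts[2:] if g]
    return gene_sets
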