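"""Bin-to-cell geometry: nucleus filtering, expansion, square assignment, aggregation.

High-resolution platforms report counts in small square capture bins
(2 µm by default) that are much smaller than a cell.  This module turns
bin-level counts plus nucleus segmentation polygons into a per-cell count
matrix:

1. abnormally large nuclei (likely segmentation fusions) are removed with a
   cutoff of mean + 2 sd on natural-log nucleus areas;
2. each square bin is assigned to the nucleus with the largest overlap,
   where overlap is approximated by counting which of a grid of subsquare
   centers (10x10 by default, i.e. 100 subsquares) fall inside the polygon;
3. nuclei are expanded about their centroid by a similarity scaling so that
   the expanded area is ``ratio`` times the nucleus area (default 2, a
   whole-cell proxy), and still-unassigned squares are assigned against the
   expanded polygons in a second pass;
4. cells whose assigned squares are empty, cover less than half of the cell
   area, or are disconnected on the bin lattice are dropped as abnormal;
5. counts are summed over each cell's assigned squares.

Coordinates are in µm, origin at the image top-left with y increasing
downward.  Square extents are half-open ``[col*s, (col+1)*s) x
[row*s, (row+1)*s)`` so adjacent squares never share points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import shapely
from scipy import sparse
from shapely.geometry import Polygon
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

PASS_NUCLEUS = "nucleus"
PASS_EXPANSION = "expansion"


class InvalidPolygonError(ValueError):
    """Raised for degenerate or self-intersecting nucleus contours."""


@dataclass(frozen=True)
class NucleusPolygon:
    """A segmented nucleus contour.

    Parameters
    ----------
    nucleus_id
        Integer label of the nucleus.
    contour
        ``(N, 2)`` array of vertex coordinates in µm, ordered along the
        ring.  The ring is closed implicitly (last vertex connects back to
        the first); a repeated closing vertex is accepted and dropped.
    """

    nucleus_id: int
    contour: np.ndarray

    _polygon: Polygon = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        contour = np.asarray(self.contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 2:
            raise InvalidPolygonError("contour must be an (N, 2) array")
        if len(contour) > 3 and np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]
        if len(contour) < 3:
            raise InvalidPolygonError(
                f"nucleus {self.nucleus_id}: contour has {len(contour)} vertices, need >= 3"
            )
        poly = Polygon(contour)
        if not poly.is_valid or poly.area <= 0.0:
            raise InvalidPolygonError(
                f"nucleus {self.nucleus_id}: contour is not a simple positive-area ring"
            )
        object.__setattr__(self, "contour", contour)
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area(self) -> float:
        """Shoelace area in µm², positive for either vertex orientation."""
        return self._polygon.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self._polygon.centroid
        return (c.x, c.y)


@dataclass(frozen=True)
class ExpansionConfig:
    """Parameters of the square-assignment stage.

    ``ratio`` is the target area ratio between the expanded (whole-cell
    proxy) and original nucleus; ``subsquare_grid`` is the per-side
    subdivision used to approximate overlap areas (10 -> 100 subsquares);
    ``bin_size`` is the square side length in µm.
    """

    ratio: float = 2.0
    subsquare_grid: int = 10
    bin_size: float = 2.0
    coverage_basis: str = "expanded"  # or "nucleus": area used in the half-coverage rule

    def __post_init__(self) -> None:
        if self.ratio < 1.0:
            raise ValueError("expansion ratio must be >= 1")
        if self.subsquare_grid < 1:
            raise ValueError("subsquare_grid must be >= 1")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.coverage_basis not in ("expanded", "nucleus"):
            raise ValueError("coverage_basis must be 'expanded' or 'nucleus'")


def polygon_area(contour: np.ndarray) -> float:
    """Area of a simple polygon in µm² (orientation-independent)."""
    return NucleusPolygon(nucleus_id=-1, contour=np.asarray(contour, float)).area


def filter_large_nuclei(nuclei: list[NucleusPolygon]) -> list[NucleusPolygon]:
    """Drop nuclei whose log-area exceeds mean + 2 sample-sd of log-areas.

    Abnormally large nuclei typically arise from merged segmentations.  The
    cutoff uses natural logs and the n-1 standard deviation; the comparison
    is strict, so a zero-variance population is never filtered.  Fewer than
    two nuclei pass through unfiltered.
    """
    if len(nuclei) < 2:
        return list(nuclei)
    log_areas = np.log([n.area for n in nuclei])
    cutoff = log_areas.mean() + 2.0 * log_areas.std(ddof=1)
    kept = [n for n, la in zip(nuclei, log_areas) if la <= cutoff]
    if len(kept) < len(nuclei):
        logger.info("filtered %d abnormally large nuclei", len(nuclei) - len(kept))
    return kept


def expand_polygon(nucleus: NucleusPolygon, ratio: float) -> NucleusPolygon:
    """Similarity-scale a nucleus contour about its centroid.

    Every vertex ``(x_i, y_i)`` maps to ``sqrt(r)*(x_i - x_0) + x_0`` (and
    likewise in y) where ``(x_0, y_0)`` is the area centroid, so the
    expanded polygon has exactly ``ratio`` times the original area and the
    same centroid.
    """
    if ratio < 1.0:
        raise ValueError("expansion ratio must be >= 1")
    cx, cy = nucleus.centroid
    center = np.array([cx, cy])
    contour = np.sqrt(ratio) * (nucleus.contour - center) + center
    return NucleusPolygon(nucleus_id=nucleus.nucleus_id, contour=contour)


def _subsquare_centers(x0: float, y0: float, side: float, grid: int) -> np.ndarray:
    """Centers of the grid x grid subsquares of [x0, x0+side) x [y0, y0+side)."""
    step = side / grid
    offs = (np.arange(grid) + 0.5) * step
    xx, yy = np.meshgrid(x0 + offs, y0 + offs)
    return np.column_stack([xx.ravel(), yy.ravel()])


def approximate_overlap(
    square_origin: tuple[float, float],
    side: float,
    polygon: Polygon,
    subsquare_grid: int = 10,
) -> int:
    """Approximate square/polygon overlap as a subsquare count in [0, grid²].

    The square is split into ``grid x grid`` equal subsquares and a
    subsquare counts as overlapping when its center point lies inside or on
    the boundary of the polygon.  ``count / grid²`` converges to the exact
    intersection-area fraction as the grid is refined.
    """
    centers = _subsquare_centers(square_origin[0], square_origin[1], side, subsquare_grid)
    pts = shapely.points(centers)
    return int(shapely.covers(polygon, pts).sum())


def _positions_frame(positions: pd.DataFrame) -> pd.DataFrame:
    required = {"barcode", "array_row", "array_col"}
    missing = required - set(positions.columns)
    if missing:
        raise ValueError(f"positions table missing columns: {sorted(missing)}")
    return positions


def assign_squares(
    positions: pd.DataFrame,
    nuclei: list[NucleusPolygon],
    config: ExpansionConfig | None = None,
) -> pd.DataFrame:
    """Two-pass assignment of square bins to nuclei.

    Pass 1 assigns every square with a positive approximate overlap to the
    argmax-overlap original nucleus; pass 2 repeats the procedure for the
    still-unassigned squares against the centroid-expanded nuclei.  Overlap
    ties are broken toward the smallest ``nucleus_id`` so the assignment is
    deterministic.  Squares overlapping nothing in either pass are left out
    of the returned table.

    Parameters
    ----------
    positions
        Table with columns ``barcode``, ``array_row``, ``array_col`` (and
        optionally ``x_um``/``y_um``, ignored here: extents are derived
        from the grid indices and ``config.bin_size``).
    nuclei
        Nuclei that already passed :func:`filter_large_nuclei`.
    config
        Expansion ratio, subsquare grid and bin size.

    Returns
    -------
    DataFrame with columns ``barcode``, ``nucleus_id``, ``pass``,
    ``overlap`` (the winning subsquare count), indexed like ``positions``.
    """
    config = config or ExpansionConfig()
    positions = _positions_frame(positions)
    side = config.bin_size

    barcodes = positions["barcode"].to_numpy()
    x0 = positions["array_col"].to_numpy(float) * side
    y0 = positions["array_row"].to_numpy(float) * side

    assigned: dict[str, tuple[int, str, int]] = {}
    remaining = np.arange(len(positions))

    for pass_label, polys in (
        (PASS_NUCLEUS, [n.polygon for n in nuclei]),
        (PASS_EXPANSION, [expand_polygon(n, config.ratio).polygon for n in nuclei]),
    ):
        if len(remaining) == 0 or not nuclei:
            break
        ids = np.array([n.nucleus_id for n in nuclei])
        tree = STRtree(polys)
        boxes = shapely.box(x0[remaining], y0[remaining], x0[remaining] + side, y0[remaining] + side)
        sq_idx, poly_idx = tree.query(boxes)  # candidate pairs by bounding box
        still = []
        # group candidate polygons per square
        order = np.argsort(sq_idx, kind="stable")
        sq_idx, poly_idx = sq_idx[order], poly_idx[order]
        bounds = np.searchsorted(sq_idx, np.arange(len(remaining) + 1))
        for local in range(len(remaining)):
            gi = remaining[local]
            cands = poly_idx[bounds[local] : bounds[local + 1]]
            if len(cands) == 0:
                still.append(gi)
                continue
            centers = _subsquare_centers(x0[gi], y0[gi], side, config.subsquare_grid)
            pts = shapely.points(centers)
            best_id, best_ov = None, 0
            for ci in cands:
                ov = int(shapely.covers(polys[ci], pts).sum())
                if ov > best_ov or (ov == best_ov and ov > 0 and ids[ci] < best_id):
                    best_ov, best_id = ov, int(ids[ci])
            if best_ov > 0:
                assigned[barcodes[gi]] = (best_id, pass_label, best_ov)
            else:
                still.append(gi)
        remaining = np.array(still, dtype=int)

    if len(remaining):
        logger.info("%d squares overlap no nucleus (original or expanded); dropped", len(remaining))

    rows = [(bc, *assigned[bc]) for bc in barcodes if bc in assigned]
    return pd.DataFrame(rows, columns=["barcode", "nucleus_id", "pass", "overlap"])


def _squares_connected(rows: np.ndarray, cols: np.ndarray) -> bool:
    """True when the (row, col) lattice cells form one 4-connected component."""
    cells = set(zip(rows.tolist(), cols.tolist()))
    if not cells:
        return False
    stack = [next(iter(cells))]
    seen = {stack[0]}
    while stack:
        r, c = stack.pop()
        for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(cells)


def detect_abnormal_cells(
    assignment: pd.DataFrame,
    positions: pd.DataFrame,
    nuclei: list[NucleusPolygon],
    config: ExpansionConfig | None = None,
) -> set[int]:
    """Identify cells whose bin assignments are structurally implausible.

    A cell is abnormal if (a) no square was assigned to its nucleus in the
    first (unexpanded) pass, (b) the total area of its assigned squares is
    below half of the cell area — the expanded-cell area ``ratio * nucleus
    area`` by default, configurable to the bare nucleus area — or (c) its
    assigned squares do not form a single 4-connected component on the bin
    lattice.
    """
    config = config or ExpansionConfig()
    pos = _positions_frame(positions).set_index("barcode")
    sq_area = config.bin_size**2

    merged = assignment.join(pos[["array_row", "array_col"]], on="barcode")
    abnormal: set[int] = set()
    by_cell = dict(tuple(merged.groupby("nucleus_id")))
    for nuc in nuclei:
        nid = nuc.nucleus_id
        grp = by_cell.get(nid)
        if grp is None or not (grp["pass"] == PASS_NUCLEUS).any():
            abnormal.add(nid)  # rule (a): nothing assigned to the bare nucleus
            continue
        cell_area = nuc.area * (config.ratio if config.coverage_basis == "expanded" else 1.0)
        if len(grp) * sq_area < 0.5 * cell_area:  # rule (b)
            abnormal.add(nid)
            continue
        if not _squares_connected(
            grp["array_row"].to_numpy(int), grp["array_col"].to_numpy(int)
        ):  # rule (c)
            abnormal.add(nid)
    return abnormal


def aggregate_counts(
    counts: sparse.spmatrix,
    gene_ids: pd.DataFrame | list[str],
    square_barcodes: list[str],
    assignment: pd.DataFrame,
    nuclei: list[NucleusPolygon],
    abnormal: set[int] | None = None,
    config: ExpansionConfig | None = None,
) -> ad.AnnData:
    """Sum bin counts over each cell's assigned squares.

    Parameters
    ----------
    counts
        Sparse genes x squares integer matrix.
    gene_ids
        Gene identifiers (list, or DataFrame whose first column is the id);
        length must match ``counts.shape[0]``.
    square_barcodes
        Barcodes of the columns of ``counts``.
    assignment
        Output of :func:`assign_squares`.
    nuclei
        Nuclei (for centroid metadata).
    abnormal
        Nucleus ids to drop, from :func:`detect_abnormal_cells`.

    Returns
    -------
    :class:`anndata.AnnData` with cells as observations and genes as
    variables; ``X`` holds the aggregated integer counts and ``obs``
    carries nucleus id, centroid, assigned-square count, covered area and
    the per-pass square composition.
    """
    config = config or ExpansionConfig()
    abnormal = abnormal or set()
    if isinstance(gene_ids, pd.DataFrame):
        gene_ids = gene_ids.iloc[:, 0].astype(str).tolist()
    counts = sparse.csc_matrix(counts)
    if counts.shape[0] != len(gene_ids):
        raise ValueError(
            f"gene-id mismatch: matrix has {counts.shape[0]} rows, sidecar {len(gene_ids)} genes"
        )
    if counts.shape[1] != len(square_barcodes):
        raise ValueError("square barcode count does not match matrix columns")

    keep = assignment[~assignment["nucleus_id"].isin(abnormal)]
    cells = sorted(keep["nucleus_id"].unique())
    cell_pos = {nid: i for i, nid in enumerate(cells)}
    col_of = {bc: j for j, bc in enumerate(square_barcodes)}

    sq_cols, cell_cols = [], []
    for bc, nid in zip(keep["barcode"], keep["nucleus_id"]):
        j = col_of.get(bc)
        if j is not None:
            sq_cols.append(j)
            cell_cols.append(cell_pos[nid])
    # genes x cells = (genes x squares) @ (squares x cells) indicator
    indicator = sparse.csc_matrix(
        (np.ones(len(sq_cols)), (sq_cols, cell_cols)), shape=(counts.shape[1], len(cells))
    )
    agg = sparse.csr_matrix((counts @ indicator).T)  # cells x genes

    nuc_by_id = {n.nucleus_id: n for n in nuclei}
    n_sq = keep.groupby("nucleus_id").size()
    n_pass1 = keep[keep["pass"] == PASS_NUCLEUS].groupby("nucleus_id").size()
    obs = pd.DataFrame(
        {
            "nucleus_id": cells,
            "centroid_x": [nuc_by_id[c].centroid[0] for c in cells],
            "centroid_y": [nuc_by_id[c].centroid[1] for c in cells],
            "n_squares": [int(n_sq.get(c, 0)) for c in cells],
            "n_squares_nucleus_pass": [int(n_pass1.get(c, 0)) for c in cells],
        },
        index=pd.Index([f"cell_{c}" for c in cells], name="cell"),
    )
    obs["covered_area_um2"] = obs["n_squares"] * config.bin_size**2
    adata = ad.AnnData(
        X=agg, obs=obs, var=pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    )
    adata.obsm["spatial"] = obs[["centroid_x", "centroid_y"]].to_numpy()
    return adata


def bins_to_cells(
    counts: sparse.spmatrix,
    gene_ids,
    square_barcodes: list[str],
    positions: pd.DataFrame,
    nuclei: list[NucleusPolygon],
    config: ExpansionConfig | None = None,
) -> tuple[ad.AnnData, pd.DataFrame, set[int]]:
    """Run the full bin-to-cell stage: filter, assign, clean, aggregate.

    Returns the per-cell count matrix, the square assignment table and the
    set of abnormal nucleus ids that were removed.
    """
    config = config or ExpansionConfig()
    kept = filter_large_nuclei(nuclei)
    assignment = assign_squares(positions, kept, config)
    abnormal = detect_abnormal_cells(assignment, positions, kept, config)
    if abnormal:
        logger.info("removed %d abnormal cells", len(abnormal))
    adata = aggregate_counts(
        counts, gene_ids, square_barcodes, assignment, kept, abnormal, config
    )
    return adata, assignment, abnormal
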