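"""Tensor-product cubic B-spline regression of expression over 2-D space.

For one cell cluster with expression matrix ``Y`` (m genes x n cells) and
cell coordinates ``S`` (n x 2), every gene is modelled as

    y_ij = alpha_i
         + sum_k1 b1_k1(s_j1) beta_i,k1,0
         + sum_k2 b2_k2(s_j2) beta_i,0,k2
         + sum_k1,k2 b1_k1(s_j1) b2_k2(s_j2) beta_i,k1,k2
         + eps_ij,    eps_ij ~ iid N(0, sigma_i^2),

where ``b_d,1 .. b_d,K+3`` are cubic B-spline bases with K equidistant
internal knots between the coordinate minimum and maximum of dimension
``d``.  The standard cubic basis on such a knot vector has K+4 functions
that sum to one everywhere; the first is dropped so the retained K+3
columns are not collinear with the intercept.  Coefficients are estimated
by least squares, and the overall regression F statistic against the
intercept-only null,

    F = [(TSS - RSS) / (p - 1)] / [RSS / (n - p)],   p = rank of the design,

is the spatial-variability test statistic.  All genes of a cluster share
one design matrix, so its factorization is computed once and reused across
genes (and across location permutations, which only reorder design rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Raised when a coordinate dimension has zero extent."""


class InsufficientCellsError(ValueError):
    """Raised when a cluster has too few cells to fit the surface."""


@dataclass(frozen=True)
class SplineBasis:
    """Per-dimension cubic B-spline bases for one cluster's coordinates."""

    n_internal_knots: int
    knots: tuple[np.ndarray, np.ndarray]  # full knot vectors, one per dimension

    @classmethod
    def from_coords(cls, coords: np.ndarray, n_internal_knots: int = 3) -> "SplineBasis":
        coords = np.asarray(coords, float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        knots = []
        for d in range(2):
            lo, hi = coords[:, d].min(), coords[:, d].max()
            if hi <= lo:
                raise DegenerateGeometryError(f"all cells share one value in dimension {d}")
            internal = np.linspace(lo, hi, n_internal_knots + 2)[1:-1]
            knots.append(np.r_[[lo] * 4, internal, [hi] * 4])
        return cls(n_internal_knots=n_internal_knots, knots=(knots[0], knots[1]))

    @property
    def n_columns_per_dim(self) -> int:
        """K + 3 retained basis functions per dimension."""
        return self.n_internal_knots + 3

    def evaluate_full(self, x: np.ndarray, dim: int) -> np.ndarray:
        """All K+4 basis functions of one dimension (partition of unity)."""
        t = self.knots[dim]
        x = np.clip(np.asarray(x, float), t[0], t[-1])
        return BSpline.design_matrix(x, t, 3).toarray()

    def evaluate(self, x: np.ndarray, dim: int) -> np.ndarray:
        """The K+3 retained basis columns (first function dropped)."""
        return self.evaluate_full(x, dim)[:, 1:]


@dataclass
class ClusterDesign:
    """Shared design matrix and factorization for all genes of a cluster."""

    basis: SplineBasis
    X: np.ndarray
    rank: int
    pinv: np.ndarray = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def build_design(
    coords: np.ndarray,
    n_internal_knots: int = 3,
    min_extra_cells: int = 10,
    basis: SplineBasis | None = None,
) -> ClusterDesign:
    """Build the intercept + main effects + interaction design matrix.

    With K internal knots the design has ``1 + 2(K+3) + (K+3)^2`` columns.
    A pseudoinverse (rank-revealing SVD) is computed once and reused for
    every gene and every permutation replicate.  Clusters with fewer than
    ``rank + min_extra_cells`` cells are rejected.

    Pass a prebuilt ``basis`` to evaluate the design at new coordinates on
    the knots of a reference configuration (not needed for permutations,
    which only reorder rows).
    """
    coords = np.asarray(coords, float)
    basis = basis or SplineBasis.from_coords(coords, n_internal_knots)
    B1 = basis.evaluate(coords[:, 0], 0)
    B2 = basis.evaluate(coords[:, 1], 1)
    n = coords.shape[0]
    inter = (B1[:, :, None] * B2[:, None, :]).reshape(n, -1)
    X = np.hstack([np.ones((n, 1)), B1, B2, inter])
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n < rank + min_extra_cells:
        raise InsufficientCellsError(
            f"cluster has {n} cells but the design needs >= {rank + min_extra_cells}"
        )
    pinv = (vt[:rank].T / s[:rank]) @ u[:, :rank].T
    return ClusterDesign(basis=basis, X=X, rank=rank, pinv=pinv)


@dataclass
class GeneSplineFit:
    """Least-squares fit of one gene's spatial surface."""

    coefficients: np.ndarray
    fitted: np.ndarray
    rss: float
    tss: float
    sigma2: float
    f_statistic: float


def _f_from_ss(tss: np.ndarray, rss: np.ndarray, n: int, p: int) -> np.ndarray:
    """Overall regression F; 0 without signal, +inf on an exact fit."""
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss - rss) / (p - 1)) / (rss / (n - p))
    f = np.where(tss <= 0, 0.0, f)
    f = np.where((rss <= 0) & (tss > 0), np.inf, f)
    return np.maximum(f, 0.0)


def fit_genes(Y: np.ndarray, design: ClusterDesign) -> dict[str, np.ndarray]:
    """Fit all genes of a cluster against the shared design.

    Parameters
    ----------
    Y
        ``(m, n)`` matrix of log-normalized expression (genes x cells).

    Returns
    -------
    dict with ``coefficients`` (m x p), ``fitted`` (m x n), ``rss``,
    ``tss``, ``sigma2`` and ``f`` (length m).  The batch result is exactly
    the per-gene result because the factorization is shared, not
    approximated.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if not np.all(np.isfinite(Y)):
        raise ValueError("expression matrix contains non-finite values")
    n, p = design.n_cells, design.rank
    if Y.shape[1] != n:
        raise ValueError(f"Y has {Y.shape[1]} cells, design has {n}")
    coef = Y @ design.pinv.T  # minimum-norm LS solution, m x p_cols
    fitted = coef @ design.X.T
    resid = Y - fitted
    rss = np.maximum(np.einsum("ij,ij->i", resid, resid), 0.0)
    centered = Y - Y.mean(axis=1, keepdims=True)
    tss = np.einsum("ij,ij->i", centered, centered)
    # round-off floor relative to the gene's magnitude: below it, a sum of
    # squares is numerically zero (constant gene / exact fit)
    msq = np.einsum("ij,ij->i", Y, Y) / n
    floor = np.finfo(float).eps ** 2 * 1e4 * n * np.maximum(msq, 1.0)
    tss = np.where(tss <= floor, 0.0, tss)
    rss = np.where(rss <= floor, 0.0, rss)
    f = _f_from_ss(tss, rss, n, p)
    sigma2 = rss / (n - p)
    return {
        "coefficients": coef,
        "fitted": fitted,
        "rss": rss,
        "tss": tss,
        "sigma2": sigma2,
        "f": f,
    }


def fit_gene(y: np.ndarray, design: ClusterDesign) -> GeneSplineFit:
    """Fit a single gene; see :func:`fit_genes`."""
    out = fit_genes(np.asarray(y, float)[None, :], design)
    return GeneSplineFit(
        coefficients=out["coefficients"][0],
        fitted=out["fitted"][0],
        rss=float(out["rss"][0]),
        tss=float(out["tss"][0]),
        sigma2=float(out["sigma2"][0]),
        f_statistic=float(out["f"][0]),
    )


def fit_cluster(
    Y: np.ndarray,
    coords: np.ndarray,
    n_internal_knots: int = 3,
) -> tuple[ClusterDesign, dict[str, np.ndarray]]:
    """Convenience wrapper: build the shared design and fit every gene."""
    design = build_design(coords, n_internal_knots)
    return design, fit_genes(Y, design)
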