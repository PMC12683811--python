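"""Nucleus geometry, square assignment and count aggregation."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon, box

from cellsvg import geometry
from cellsvg.geometry import (
    ExpansionConfig,
    InvalidPolygonError,
    NucleusPolygon,
    approximate_overlap,
    assign_squares,
    detect_abnormal_cells,
    expand_polygon,
    filter_large_nuclei,
    polygon_area,
)

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)


def random_simple_polygon(rng, n_vertices=None, radius=3.0):
    """Random simple polygon: jittered star ring around a random center."""
    n = int(n_vertices or rng.integers(3, 15))
    while True:
        angles = 2 * np.pi * (np.arange(n) + rng.uniform(-0.3, 0.3, n)) / n
        radii = radius * rng.uniform(0.4, 1.0, n)
        center = rng.uniform(-10, 10, 2)
        contour = center + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        if Polygon(contour).is_valid:
            return contour


class TestPolygonArea:
    @pytest.mark.parametrize(
        "contour,expected",
        [
            (UNIT_SQUARE, 1.0),
            (np.array([[0, 0], [4, 0], [0, 3]], float), 6.0),
            (UNIT_SQUARE[::-1], 1.0),  # orientation invariance
        ],
    )
    def test_known_areas(self, contour, expected):
        assert polygon_area(contour) == pytest.approx(expected)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(InvalidPolygonError):
            polygon_area(np.array([[0, 0], [1, 1]], float))

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        with pytest.raises(InvalidPolygonError):
            polygon_area(bowtie)


class TestLargeNucleusFilter:
    def _nuclei_with_log_areas(self, log_areas):
        # squares with side sqrt(e^la) have the requested log-areas
        return [
            NucleusPolygon(i, UNIT_SQUARE * np.sqrt(np.exp(la)))
            for i, la in enumerate(log_areas)
        ]

    def test_zero_variance_keeps_all(self):
        nuclei = self._nuclei_with_log_areas([1.0] * 10)
        assert len(filter_large_nuclei(nuclei)) == 10

    def test_single_outlier_removed(self):
        # cutoff = mean + 2*sample sd = 1.4 + 2*1.2649 ~ 3.93 < 5
        nuclei = self._nuclei_with_log_areas([1.0] * 9 + [5.0])
        kept = filter_large_nuclei(nuclei)
        assert [n.nucleus_id for n in kept] == list(range(9))

    def test_extreme_value_inflates_its_own_cutoff(self):
        # cutoff = 2 + 2*sqrt(20) ~ 10.94 > 10: nothing removed
        nuclei = self._nuclei_with_log_areas([0.0] * 4 + [10.0])
        assert len(filter_large_nuclei(nuclei)) == 5

    def test_single_nucleus_passes_through(self):
        nuclei = self._nuclei_with_log_areas([3.0])
        assert len(filter_large_nuclei(nuclei)) == 1


class TestExpansion:
    def test_identity_at_ratio_one(self):
        nucleus = NucleusPolygon(0, UNIT_SQUARE)
        expanded = expand_polygon(nucleus, 1.0)
        np.testing.assert_allclose(expanded.contour, UNIT_SQUARE)

    def test_unit_square_doubling(self):
        expanded = expand_polygon(NucleusPolygon(0, UNIT_SQUARE), 2.0)
        assert expanded.area == pytest.approx(2.0, abs=1e-12)
        # first vertex moves radially out from the centroid (0.5, 0.5)
        np.testing.assert_allclose(expanded.contour[0], [-0.20710678, -0.20710678], atol=1e-8)

    @pytest.mark.parametrize("ratio", [1.0, 1.5, 2.0, 3.0, 4.0])
    def test_area_ratio_exact_on_random_polygons(self, rng, ratio):
        for _ in range(200):
            nucleus = NucleusPolygon(0, random_simple_polygon(rng))
            expanded = expand_polygon(nucleus, ratio)
            assert abs(expanded.area / nucleus.area - ratio) < 1e-9
            np.testing.assert_allclose(expanded.centroid, nucleus.centroid, atol=1e-9)


class TestApproximateOverlap:
    def test_full_containment_is_grid_squared(self):
        big = Polygon([(-10, -10), (10, -10), (10, 10), (-10, 10)])
        assert approximate_overlap((0.0, 0.0), 2.0, big, 10) == 100

    def test_disjoint_is_zero(self):
        far = Polygon([(50, 50), (60, 50), (55, 60)])
        assert approximate_overlap((0.0, 0.0), 2.0, far, 10) == 0

    def test_half_covered_square(self):
        # rectangle covering exactly x < 1: 5 of the 10 center columns qualify
        half = Polygon([(-5, -5), (1, -5), (1, 5), (-5, 5)])
        assert approximate_overlap((0.0, 0.0), 2.0, half, 10) == 50

    def test_converges_to_exact_area_fraction(self, rng):
        devs = []
        for _ in range(30):
            contour = random_simple_polygon(rng, radius=2.5)
            hull = shapely.convex_hull(Polygon(contour))
            approx = approximate_overlap((0.0, 0.0), 2.0, hull, 100) / 100**2
            exact = hull.intersection(box(0, 0, 2, 2)).area / 4.0
            devs.append(abs(approx - exact))
        assert np.mean(devs) < 0.01


def _positions(cells):
    return pd.DataFrame(
        [(f"s_{r}_{c}", r, c) for r, c in cells],
        columns=["barcode", "array_row", "array_col"],
    )


class TestAssignment:
    def test_single_nucleus_first_pass(self):
        nucleus = NucleusPolygon(5, UNIT_SQUARE * 6)  # covers [0,6]^2
        out = assign_squares(_positions([(1, 1)]), [nucleus])
        assert out.iloc[0]["nucleus_id"] == 5
        assert out.iloc[0]["pass"] == geometry.PASS_NUCLEUS

    def test_tie_broken_by_smaller_id(self):
        # two congruent nuclei symmetric about the square at rows 0, cols 0..1
        left = NucleusPolygon(7, np.array([[-4, 0], [1, 0], [1, 2], [-4, 2]], float))
        right = NucleusPolygon(3, np.array([[1, 0], [6, 0], [6, 2], [1, 2]], float))
        out = assign_squares(_positions([(0, 0)]), [left, right])
        assert out.iloc[0]["nucleus_id"] == 3

    def test_expansion_pass_catches_outside_square(self):
        # square center at (9,1): outside the nucleus [0,8]x[0,8] but inside
        # its expansion (sqrt(2)-scaled about (4,4) reaches x ~ 9.66)
        nucleus = NucleusPolygon(0, UNIT_SQUARE * 8)
        out = assign_squares(_positions([(0, 4)]), [nucleus], ExpansionConfig(ratio=2.0))
        assert len(out) == 1
        assert out.iloc[0]["pass"] == geometry.PASS_EXPANSION

    def test_no_overlap_square_dropped(self):
        nucleus = NucleusPolygon(0, UNIT_SQUARE * 2)
        out = assign_squares(_positions([(50, 50)]), [nucleus])
        assert len(out) == 0

    def test_deterministic(self, small_bin_sim):
        a = assign_squares(small_bin_sim["positions"], small_bin_sim["nuclei"])
        b = assign_squares(small_bin_sim["positions"], small_bin_sim["nuclei"])
        pd.testing.assert_frame_equal(a, b)

    def test_agrees_with_exact_area_assignment(self, small_bin_sim):
        """At grid 10, assignment matches exact polygon-clipping argmax for >=99% of squares."""
        nuclei = small_bin_sim["nuclei"]
        positions = small_bin_sim["positions"]
        out = assign_squares(positions, nuclei).set_index("barcode")
        polys = {n.nucleus_id: n.polygon for n in nuclei}
        expanded = {n.nucleus_id: expand_polygon(n, 2.0).polygon for n in nuclei}
        agree = total = 0
        for _, row in positions.iterrows():
            cell_box = box(row.array_col * 2.0, row.array_row * 2.0,
                           row.array_col * 2.0 + 2.0, row.array_row * 2.0 + 2.0)
            for phase in (polys, expanded):
                areas = {nid: p.intersection(cell_box).area for nid, p in phase.items()}
                best = max(sorted(areas), key=lambda nid: (areas[nid], -nid))
                if areas[best] > 1e-12:
                    total += 1
                    got = out.loc[row.barcode, "nucleus_id"] if row.barcode in out.index else None
                    agree += got == best
                    break
            else:
                total += 1
                agree += row.barcode not in out.index
        assert total > 0
        assert agree / total >= 0.99


class TestAbnormalCells:
    def test_unassigned_nucleus_flagged(self):
        near = NucleusPolygon(0, UNIT_SQUARE * 4)
        far = NucleusPolygon(1, UNIT_SQUARE * 4 + 100)
        positions = _positions([(0, 0), (0, 1), (1, 0), (1, 1)])
        assignment = assign_squares(positions, [near, far])
        abnormal = detect_abnormal_cells(assignment, positions, [near, far])
        assert 1 in abnormal and 0 not in abnormal

    def test_connectivity_rule(self):
        nucleus = NucleusPolygon(0, UNIT_SQUARE * 6)
        positions = _positions([(0, 0), (0, 1), (2, 2)])
        config = ExpansionConfig(coverage_basis="nucleus")
        # adjacent pair only: connected
        adj = pd.DataFrame({"barcode": ["s_0_0", "s_0_1"], "nucleus_id": 0,
                            "pass": geometry.PASS_NUCLEUS, "overlap": 100})
        ok = detect_abnormal_cells(adj, positions, [nucleus], config)
        # diagonal-only pair: disconnected
        diag = pd.DataFrame({"barcode": ["s_0_0", "s_2_2"], "nucleus_id": 0,
                             "pass": geometry.PASS_NUCLEUS, "overlap": 100})
        bad = detect_abnormal_cells(diag, positions, [nucleus], config)
        assert 0 in bad
        # rule (b) may still fire for the adjacent pair against a 36 µm² nucleus
        assert (0 in ok) == (2 * 4.0 < 0.5 * nucleus.area)

    def test_half_coverage_rule_uses_expanded_area(self):
        nucleus = NucleusPolygon(0, UNIT_SQUARE * 4)  # 16 µm²; expanded 32 µm²
        positions = _positions([(0, 0), (0, 1), (1, 0)])
        assignment = pd.DataFrame({"barcode": ["s_0_0", "s_0_1", "s_1_0"], "nucleus_id": 0,
                                   "pass": geometry.PASS_NUCLEUS, "overlap": 100})
        # 3 squares x 4 µm² = 12 < 16 = half the expanded area -> abnormal
        assert 0 in detect_abnormal_cells(assignment, positions, [nucleus])
        # against the bare nucleus area: 12 >= 8 -> normal
        config = ExpansionConfig(coverage_basis="nucleus")
        assert 0 not in detect_abnormal_cells(assignment, positions, [nucleus], config)


class TestAggregation:
    def test_counts_summed_per_cell(self, small_bin_sim):
        s = small_bin_sim
        adata, assignment, abnormal = geometry.bins_to_cells(
            s["counts"], [f"gene_{i}" for i in range(s["config"].n_genes)],
            s["positions"]["barcode"].tolist(), s["positions"], s["nuclei"],
        )
        # conservation: output total equals the total over assigned squares
        col_of = {bc: j for j, bc in enumerate(s["positions"]["barcode"])}
        keep = assignment[~assignment["nucleus_id"].isin(abnormal)]
        expected = sum(s["counts"][:, col_of[bc]].sum() for bc in keep["barcode"])
        assert adata.X.sum() == expected

    def test_exact_recovery_without_scatter(self, small_bin_sim):
        """Well-separated cells with no background scatter recover true totals."""
        s = small_bin_sim
        adata, _, abnormal = geometry.bins_to_cells(
            s["counts"], [f"gene_{i}" for i in range(s["config"].n_genes)],
            s["positions"]["barcode"].tolist(), s["positions"], s["nuclei"],
        )
        assert not abnormal
        totals = np.asarray(adata.X.sum(axis=1)).ravel()
        by_id = dict(zip(adata.obs["nucleus_id"], totals))
        kept_ids = {n.nucleus_id for n in filter_large_nuclei(s["nuclei"])}
        assert set(by_id) == kept_ids
        for j in kept_ids:
            assert by_id[j] == s["cell_totals"][j].sum()

    def test_gene_sidecar_mismatch_rejected(self, small_bin_sim):
        s = small_bin_sim
        with pytest.raises(ValueError, match="gene-id mismatch"):
            geometry.aggregate_counts(
                s["counts"], ["only_one_gene"], s["positions"]["barcode"].tolist(),
                assign_squares(s["positions"], s["nuclei"]), s["nuclei"],
            )
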