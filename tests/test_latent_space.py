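"""Latent-plane regions: membership, classification, fitting, persistence."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon as ShapelyPolygon

from flvae import latent_space as ls
from flvae.data import (
    STATE_NO_THROMBUS,
    STATE_PARTIAL,
    STATE_THROMBOSED,
    LatentPoint,
)

UNIT_SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]


def winding_number_inside(p, verts):
    """Brute-force winding-number membership oracle (interior points)."""
    angles = 0.0
    n = len(verts)
    for i in range(n):
        a = np.asarray(verts[i]) - p
        b = np.asarray(verts[(i + 1) % n]) - p
        angles += np.arctan2(a[0] * b[1] - a[1] * b[0], np.dot(a, b))
    return abs(angles) > np.pi  # ~2*pi inside, ~0 outside


class TestPointInPolygon:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.5, 0.5), True),
            ((2.0, 2.0), False),
            ((1.0, 0.5), True),  # on an edge: boundary counts as inside
            ((0.0, 0.0), True),  # on a vertex
            ((-1e-9, 0.5), False),
        ],
    )
    def test_unit_square_membership(self, p, expected):
        assert ls.point_in_polygon(p, UNIT_SQUARE) is expected

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ls.point_in_polygon((0, 0), [(0, 0), (1, 1), (2, 2)])

    def test_agrees_with_winding_number_oracle(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        while n_checked < 1000:
            pts = rng.normal(size=(rng.integers(4, 10), 2)) * rng.uniform(0.5, 3)
            try:
                hull = ConvexHull(pts)
            except Exception:
                continue
            verts = pts[hull.vertices]
            p = rng.normal(size=2) * 2
            poly = ShapelyPolygon(verts)
            if poly.exterior.distance(Point(p)) < 1e-9:
                continue  # boundary convention differs; tested separately
            assert ls.point_in_polygon(p, verts) == winding_number_inside(p, verts)
            n_checked += 1


def make_regions():
    return ls.RegionSet(
        no_thrombus_polygon=np.array([(-1, -1), (1, -1), (1, 1), (-1, 1)], float),
        thrombosed_polygon=np.array([(3, 3), (5, 3), (5, 5), (3, 5)], float),
    )


class TestRegionSetAndClassify:
    def test_overlapping_polygons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ls.RegionSet(
                no_thrombus_polygon=np.array(UNIT_SQUARE, float),
                thrombosed_polygon=np.array(UNIT_SQUARE, float) + 0.5,
            )

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            ls.RegionSet(
                no_thrombus_polygon=np.array([(0, 0), (1, 1)], float),
                thrombosed_polygon=np.array([(3, 3), (5, 3), (4, 5)], float),
            )

    def test_three_way_classification(self):
        regions = make_regions()
        assert ls.classify(LatentPoint(0.0, 0.0), regions) == STATE_NO_THROMBUS
        assert ls.classify(LatentPoint(4.0, 4.0), regions) == STATE_THROMBOSED
        assert ls.classify(LatentPoint(2.0, 2.0), regions) == STATE_PARTIAL

    def test_shared_boundary_resolved_by_precedence(self):
        # polygons may touch along an edge (zero-area intersection); a point
        # on the shared edge is inside both and no_thrombus must win
        regions = ls.RegionSet(
            no_thrombus_polygon=np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float),
            thrombosed_polygon=np.array([(1, 0), (2, 0), (2, 1), (1, 1)], float),
        )
        assert ls.classify(LatentPoint(1.0, 0.5), regions) == STATE_NO_THROMBUS

    @given(x=st.floats(-10, 10), y=st.floats(-10, 10))
    def test_classification_is_total(self, x, y):
        label = ls.classify(LatentPoint(x, y), make_regions())
        assert label in (STATE_NO_THROMBUS, STATE_PARTIAL, STATE_THROMBOSED)


class TestFitRegions:
    def test_separated_clusters_give_consistent_regions(self):
        rng = np.random.default_rng(0)
        near = rng.normal(0, 0.3, size=(20, 2))
        far = rng.normal(5, 0.3, size=(20, 2))
        labeled = [(p, STATE_NO_THROMBUS) for p in near] + [
            (p, STATE_THROMBOSED) for p in far
        ]
        regions = ls.fit_regions(labeled, margin=0.1)
        for p, lab in labeled:
            assert ls.classify(LatentPoint(*p), regions) == lab

    def test_collinear_points_rejected(self):
        labeled = [((i, i), STATE_NO_THROMBUS) for i in range(3)] + [
            ((5 + i, 1), STATE_THROMBOSED) for i in range(3)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            ls.fit_regions(labeled)

    def test_insufficient_points_rejected(self):
        labeled = [((0, 0), STATE_NO_THROMBUS), ((1, 0), STATE_NO_THROMBUS)] + [
            ((5, 5), STATE_THROMBOSED)
        ] * 4
        with pytest.raises(ValueError, match=">= 3"):
            ls.fit_regions(labeled)

    def test_zero_margin_hull_vertices_are_input_points(self):
        rng = np.random.default_rng(1)
        near = rng.normal(0, 0.5, size=(10, 2))
        far = rng.normal(6, 0.5, size=(10, 2))
        labeled = [(p, STATE_NO_THROMBUS) for p in near] + [
            (p, STATE_THROMBOSED) for p in far
        ]
        regions = ls.fit_regions(labeled, margin=0.0)
        all_pts = {tuple(p) for p in np.vstack([near, far])}
        for v in np.vstack(
            [regions.no_thrombus_polygon, regions.thrombosed_polygon]
        ):
            assert tuple(v) in all_pts

    def test_overlapping_hulls_after_dilation_rejected(self):
        rng = np.random.default_rng(2)
        near = rng.normal(0, 0.5, size=(10, 2))
        close = rng.normal(1.5, 0.5, size=(10, 2))
        labeled = [(p, STATE_NO_THROMBUS) for p in near] + [
            (p, STATE_THROMBOSED) for p in close
        ]
        with pytest.raises(ValueError, match="overlap"):
            ls.fit_regions(labeled, margin=2.0)

    def test_holdout_reference_slices_classified_correctly(self, ref_model):
        """Held-out thrombus-state recovery with calibrated regions."""
        model, regions, series, truth = ref_model
        by_key = {(s.patient_id, s.timepoint): s for s in series}
        ref = truth[truth["state"].isin([STATE_NO_THROMBUS, STATE_THROMBOSED])]
        hits = 0
        for row in ref.itertuples():
            sl = by_key[(row.patient_id, row.timepoint)].slices[row.slice_index]
            hits += ls.classify(model.encode(sl), regions) == row.state
        assert hits / len(ref) >= 0.9  # frozen regression threshold


class TestPersistence:
    def test_roundtrip_preserves_vertices(self, tmp_path):
        regions = make_regions()
        path = str(tmp_path / "regions.json")
        ls.save_regions(regions, path)
        back = ls.load_regions(path)
        np.testing.assert_array_equal(
            back.no_thrombus_polygon, regions.no_thrombus_polygon
        )
        np.testing.assert_array_equal(
            back.thrombosed_polygon, regions.thrombosed_polygon
        )

    def test_malformed_file_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            ls.load_regions(str(p))

    def test_missing_polygon_entry_rejected(self, tmp_path):
        p = tmp_path / "bad2.json"
        p.write_text('{"version": 1, "no_thrombus_polygon": [[0,0],[1,0],[0,1]]}')
        with pytest.raises(ValueError, match="missing"):
            ls.load_regions(str(p))

    def test_overlapping_polygons_in_file_rejected(self, tmp_path):
        import json

        p = tmp_path / "overlap.json"
        sq = [[0, 0], [2, 0], [2, 2], [0, 2]]
        p.write_text(
            json.dumps(
                {"version": 1, "no_thrombus_polygon": sq, "thrombosed_polygon": sq}
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            ls.load_regions(str(p))
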