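import json

import numpy as np
import pytest

import spatentropy as se
from spatentropy.errors import (
    ContainmentError,
    GeometryError,
    ParameterError,
    ParseError,
)


class TestWindow:
    @pytest.mark.parametrize(
        "vertices, area",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
            ([(0, 0), (1, 0), (0, 1)], 0.5),
            ([(0, 1), (1, 0), (0, 0)], 0.5),  # reversed orientation
        ],
    )
    def test_shoelace_area(self, vertices, area):
        win = se.ObservationWindow.from_vertices(vertices)
        assert se.window_area(win) == pytest.approx(area, rel=1e-9)

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(GeometryError):
            se.ObservationWindow.from_vertices(
                [(0, 0), (1, 1), (1, 0), (0, 1)])  # bow-tie

    def test_boundary_counts_as_inside(self, unit_square):
        assert unit_square.covers(0.0, 0.5)
        assert unit_square.covers(1.0, 1.0)


class TestPointPatternIO:
    def test_read_csv_with_marks(self, tmp_path, unit_square):
        pts = tmp_path / "pts.csv"
        pts.write_text("x,y,group\n0.1,0.2,a\n0.3,0.4,b\n0.5,0.6,a\n")
        win = tmp_path / "w.wkt"
        win.write_text(unit_square.to_wkt())
        pat = se.read_point_pattern(pts, win, mark_column="group")
        assert pat.n == 3
        assert list(pat.marks) == ["a", "b", "a"]

    def test_empty_csv_gives_empty_pattern(self, tmp_path, unit_square):
        pts = tmp_path / "pts.csv"
        pts.write_text("x,y\n")
        pat = se.read_point_pattern(pts, unit_square)
        assert pat.n == 0

    def test_outside_point_raises_unless_dropped(self, tmp_path, unit_square):
        pts = tmp_path / "pts.csv"
        pts.write_text("x,y\n0.5,0.5\n2,2\n")
        with pytest.raises(ContainmentError):
            se.read_point_pattern(pts, unit_square)
        pat = se.read_point_pattern(pts, unit_square, drop_outside=True)
        assert pat.n == 1

    def test_malformed_csv(self, tmp_path, unit_square):
        pts = tmp_path / "pts.csv"
        pts.write_text("lon,lat\n1,2\n")
        with pytest.raises(ParseError):
            se.read_point_pattern(pts, unit_square)

    def test_window_wkt_and_geojson_agree(self, tmp_path, unit_square):
        wkt = tmp_path / "w.wkt"
        wkt.write_text(unit_square.to_wkt())
        gj = tmp_path / "w.geojson"
        gj.write_text(json.dumps({
            "type": "Feature", "properties": {},
            "geometry": {"type": "Polygon",
                         "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1],
                                          [0, 0]]]}}))
        assert se.read_window(wkt).area == pytest.approx(
            se.read_window(gj).area)

    def test_points_csv_round_trip(self, tmp_path, marked_csr_pattern):
        path = tmp_path / "pts.csv"
        se.write_points_csv(marked_csr_pattern, path, mark_name="m")
        back = se.read_point_pattern(path, marked_csr_pattern.window,
                                     mark_column="m")
        np.testing.assert_array_equal(back.coords, marked_csr_pattern.coords)
        assert list(back.marks) == list(marked_csr_pattern.marks)


class TestAsciiGrid:
    @pytest.mark.parametrize("ystep", [1.0, 2.5])
    def test_round_trip_both_dialects(self, tmp_path, small_raster, ystep):
        small_raster.ystep = ystep
        path = tmp_path / "g.asc"
        se.write_ascii_grid(small_raster, path)
        text = path.read_text()
        assert ("cellsize" in text) == (ystep == 1.0)  # dx/dy only when needed
        back = se.read_ascii_grid(path)
        np.testing.assert_array_equal(back.values[~back.mask],
                                      small_raster.values[~small_raster.mask])
        np.testing.assert_array_equal(back.mask, small_raster.mask)
        assert back.ystep == pytest.approx(ystep)
        assert back.origin == small_raster.origin

    def test_header_validation(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows 1\n0 1\n")
        with pytest.raises(ParseError):
            se.read_ascii_grid(path)

    def test_nodata_padding_changes_nothing(self, small_raster):
        """Extra NODATA rows never affect any downstream statistic."""
        padded = se.CategoricalRaster(
            np.vstack([small_raster.values, np.zeros((2, 6), int)]),
            np.vstack([small_raster.mask, np.ones((2, 6), bool)]))
        for rast in (small_raster,):
            h0 = se.shannon_entropy(se.tabulate(rast)).value
            h1 = se.shannon_entropy(se.tabulate(padded)).value
            assert h0 == pytest.approx(h1, abs=1e-15)
            o0 = se.oneill_entropy(rast).value
            o1 = se.oneill_entropy(padded).value
            assert o0 == pytest.approx(o1, abs=1e-15)


class TestPixellate:
    def test_single_point_single_presence_cell(self, unit_square):
        pat = se.PointPattern([(0.31, 0.77)], unit_square)
        rast = se.pixellate(pat, 10, 10)
        assert (rast.values[~rast.mask] == 1).sum() == 1

    def test_multiplicity_collapses(self, unit_square):
        pat = se.PointPattern([(0.31, 0.77), (0.32, 0.78)], unit_square)
        rast = se.pixellate(pat, 10, 10)
        assert (rast.values[~rast.mask] == 1).sum() == 1

    def test_presence_cells_never_exceed_n(self, csr_pattern):
        for res in (7, 20, 53):
            rast = se.pixellate(csr_pattern, res, res)
            occ = (rast.values[~rast.mask] == 1).sum()
            assert occ <= csr_pattern.n

    def test_cells_outside_window_masked(self):
        triangle = se.ObservationWindow.from_vertices([(0, 0), (1, 0), (0, 1)])
        pat = se.PointPattern([(0.1, 0.1)], triangle)
        rast = se.pixellate(pat, 10, 10)
        # roughly half the bbox is outside the triangle
        assert rast.mask.sum() > 30
        assert rast.n_valid + rast.mask.sum() == 100


class TestVoronoi:
    def test_single_generator_returns_window(self, unit_square):
        part = se.voronoi_partition(unit_square, 1, seed=0)
        assert part.G == 1
        assert part.sub_areas[0].size == pytest.approx(unit_square.area)

    def test_two_fixed_generators_split_square_in_halves(self, unit_square):
        part = se.voronoi_partition_from_points(
            unit_square, [(0.25, 0.5), (0.75, 0.5)])
        assert sorted(sa.size for sa in part.sub_areas) == pytest.approx(
            [0.5, 0.5])

    def test_sizes_conserve_window_area(self, unit_square):
        part = se.voronoi_partition(unit_square, 10, seed=3)
        assert sum(sa.size for sa in part.sub_areas) == pytest.approx(
            unit_square.area, rel=1e-6)

    def test_deterministic_given_seed(self, unit_square):
        a = se.voronoi_partition(unit_square, 8, seed=11)
        b = se.voronoi_partition(unit_square, 8, seed=11)
        np.testing.assert_array_equal(a.generators, b.generators)
        assert [sa.size for sa in a.sub_areas] == [sa.size for sa in b.sub_areas]
        c = se.voronoi_partition(unit_square, 8, seed=12)
        assert not np.allclose(a.generators, c.generators)

    def test_assignment_ties_break_to_lowest_id(self, unit_square):
        part = se.voronoi_partition_from_points(
            unit_square, [(0.25, 0.5), (0.75, 0.5)])
        pat = se.PointPattern([(0.5, 0.5)], unit_square)  # equidistant
        assert part.assign(pat)[0] == 0


class TestRasterPartitions:
    def test_quantile_partition_quarters_1_to_100(self):
        rast = se.CategoricalRaster(np.arange(1, 101).reshape(10, 10),
                                    np.zeros((10, 10), bool))
        part = se.quantile_partition(rast, 4)
        assert part.G == 4
        assert [sa.size for sa in part.sub_areas] == [25.0] * 4

    def test_quantile_partition_constant_raster_errors(self):
        rast = se.CategoricalRaster(np.ones((4, 4)), np.zeros((4, 4), bool))
        with pytest.raises(ParameterError, match="elev"):
            se.quantile_partition(rast, 4, covariate="elev")

    def test_checkerboard_class_partition(self):
        values = np.indices((4, 4)).sum(axis=0) % 2
        part = se.raster_class_partition(
            se.CategoricalRaster(values, np.zeros((4, 4), bool)))
        assert part.G == 2
        assert [sa.size for sa in part.sub_areas] == [8.0, 8.0]

    def test_single_category_gives_G1(self):
        part = se.raster_class_partition(
            se.CategoricalRaster(np.zeros((3, 3), int), np.zeros((3, 3), bool)))
        assert part.G == 1

    def test_all_nodata_errors(self):
        with pytest.raises(GeometryError):
            se.raster_class_partition(
                se.CategoricalRaster(np.zeros((2, 2), int), np.ones((2, 2), bool)))


class TestPartitionGeoJSON:
    def test_round_trip_and_conservation(self, tmp_path, unit_square):
        from spatentropy.geometry import partition_to_geojson

        part = se.voronoi_partition(unit_square, 5, seed=2)
        path = tmp_path / "part.geojson"
        partition_to_geojson(part, path)
        back = se.read_partition_geojson(path, window=unit_square)
        assert back.G == 5
        assert sum(sa.size for sa in back.sub_areas) == pytest.approx(
            unit_square.area, rel=1e-6)
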