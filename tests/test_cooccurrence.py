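import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spatentropy as se
from spatentropy.errors import EmptyTableError, ParameterError


def brute_force_distance_couples(coords, values, d):
    """O(n^2) oracle: unordered pairs within d, canonical coordinate order."""
    order = sorted(range(len(coords)),
                   key=lambda i: (coords[i][0], coords[i][1], i))
    counts: dict = {}
    for a, b in itertools.combinations(order, 2):
        dist = np.hypot(coords[a][0] - coords[b][0], coords[a][1] - coords[b][1])
        if dist <= d:
            counts[(values[a], values[b])] = counts.get(
                (values[a], values[b]), 0) + 1
    return counts


class TestContiguousCouples:
    def test_1x2_single_couple(self):
        rast = se.CategoricalRaster(np.array([[0, 1]]), np.zeros((1, 2), bool))
        table = se.contiguous_couples(rast)
        assert table.total_pairs == 1
        assert table.counts[0, 1] == 1

    def test_2x2_checkerboard_hand_enumeration(self):
        rast = se.CategoricalRaster(np.array([[0, 1], [1, 0]]),
                                    np.zeros((2, 2), bool))
        table = se.contiguous_couples(rast)
        assert table.total_pairs == 4
        assert table.counts[0, 1] == 2 and table.counts[1, 0] == 2
        assert table.counts[0, 0] == 0 and table.counts[1, 1] == 0

    def test_nodata_blocks_adjacency(self):
        mask = np.array([[False, True, False]])
        rast = se.CategoricalRaster(np.array([[0, 0, 1]]), mask)
        with pytest.raises(EmptyTableError):
            se.contiguous_couples(rast)

    def test_symmetric_enumeration_counts_match(self, small_raster):
        table = se.contiguous_couples(small_raster, symmetrise=True)
        assert table.counts[0, 1] == table.counts[1, 0]


class TestOneillFamily:
    COUNTS = [39775, 919, 919, 179]

    def table(self, counts=None):
        return se.CooccurrenceTable.from_counts(
            [0, 1], counts or self.COUNTS, {"rule": "contiguity"})

    def test_printed_relative_values(self):
        assert se.oneill_entropy(self.table()).relative == pytest.approx(
            0.17, abs=0.01)
        assert se.contagion(self.table()).value == pytest.approx(0.83, abs=0.01)
        assert se.parresol_edwards(self.table()).relative == pytest.approx(
            0.17, abs=0.01)

    @pytest.mark.parametrize(
        "counts, rel",
        [([100, 0, 0, 0], 0.0), ([25, 25, 25, 25], 1.0)],
    )
    def test_degenerate_and_uniform(self, counts, rel):
        assert se.oneill_entropy(self.table(counts)).relative == pytest.approx(rel)
        assert se.contagion(self.table(counts)).value == pytest.approx(1 - rel)

    @given(st.lists(st.integers(0, 5000), min_size=4, max_size=4
                    ).filter(lambda c: sum(c) > 0))
    def test_identities_exact(self, counts):
        table = self.table(counts)
        o = se.oneill_entropy(table)
        assert se.contagion(table).value + o.relative == pytest.approx(1.0,
                                                                       abs=0)
        assert se.parresol_edwards(table).value == -o.value
        assert 0 <= o.value <= np.log(4) + 1e-9

    def test_distance_table_rejected(self):
        table = se.CooccurrenceTable.from_counts([0, 1], [1, 2, 3, 4],
                                                 {"rule": "distance"})
        with pytest.raises(ParameterError):
            se.oneill_entropy(table)


class TestDistanceSummaries:
    def test_two_points(self, unit_square):
        pat = se.PointPattern([(0.1, 0.5), (0.4, 0.5)], unit_square)
        ds = se.distance_summaries(pat)
        np.testing.assert_allclose(ds.nn_distances, [0.3, 0.3])
        np.testing.assert_allclose(ds.pairwise_distances, [0.3])

    def test_collinear_hand_values(self, unit_square):
        pat = se.PointPattern([(0, 0), (0.1, 0), (0.3, 0)], unit_square)
        ds = se.distance_summaries(pat)
        np.testing.assert_allclose(ds.nn_distances, [0.1, 0.1, 0.2])
        np.testing.assert_allclose(sorted(ds.pairwise_distances),
                                   [0.1, 0.2, 0.3])

    def test_single_point_errors(self, unit_square):
        with pytest.raises(ParameterError):
            se.distance_summaries(se.PointPattern([(0.5, 0.5)], unit_square))


class TestDistanceCouples:
    def test_three_point_hand_enumeration(self, unit_square):
        pat = se.PointPattern([(0.1, 0.1), (0.2, 0.1), (0.15, 0.2)],
                              unit_square, ["a", "b", "b"])
        table = se.distance_couples(pat, d=0.5)
        assert table.total_pairs == 3
        # canonical x-order: a(0.1), b(0.15, y=0.2), b(0.2)
        assert table.counts[0, 1] == 2  # a-b twice
        assert table.counts[1, 1] == 1  # b-b once

    def test_below_minimum_distance_errors_with_min(self, unit_square):
        pat = se.PointPattern([(0.1, 0.1), (0.4, 0.1)], unit_square,
                              ["a", "b"])
        with pytest.raises(EmptyTableError) as err:
            se.distance_couples(pat, d=0.1)
        assert err.value.min_distance == pytest.approx(0.3)

    @given(st.lists(
        st.tuples(st.integers(0, 12), st.integers(0, 12), st.integers(0, 2)),
        min_size=2, max_size=40),
        st.floats(0.5, 10.0))
    def test_matches_brute_force_oracle(self, triples, d):
        big = se.ObservationWindow.from_vertices(
            [(0, 0), (12, 0), (12, 12), (0, 12)])
        coords = [(x, y) for x, y, _ in triples]
        values = [f"c{m}" for _, _, m in triples]
        pat = se.PointPattern(coords, big, values)
        expected = brute_force_distance_couples(coords, values, d)
        if not expected:
            with pytest.raises(EmptyTableError):
                se.distance_couples(pat, d)
            return
        table = se.distance_couples(pat, d)
        got = {}
        for i, a in enumerate(table.categories):
            for j, b in enumerate(table.categories):
                if table.counts[i, j]:
                    got[(a, b)] = table.counts[i, j]
        assert got == expected

    def test_grid_distance_at_cell_size_matches_contiguity(self, small_raster):
        """d = cell size reaches exactly the rook neighbours (diagonals are
        at cell * sqrt(2) > cell), so the unordered pair multisets agree."""
        tc = se.contiguous_couples(small_raster)
        td = se.distance_couples(small_raster, d=1.0)
        np.testing.assert_array_equal(tc.counts + tc.counts.T,
                                      td.counts + td.counts.T)
        assert tc.total_pairs == td.total_pairs

    def test_symmetrise_preserves_totals(self, unit_square, marked_csr_pattern):
        table = se.distance_couples(marked_csr_pattern, d=0.1)
        sym = table.symmetrised()
        assert sym.total_pairs == table.total_pairs
        assert sym.counts[0, 1] == sym.counts[1, 0]
        assert sym.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestLeibovici:
    @pytest.mark.parametrize(
        "cats, counts, rel",
        [
            (["maj", "min"], [4334, 3780, 3835, 3404], 0.99),
            ([0, 1], [18262284, 501725, 514686, 22427], 0.18),
        ],
    )
    def test_printed_relative_values(self, cats, counts, rel):
        table = se.CooccurrenceTable.from_counts(cats, counts,
                                                 {"rule": "distance", "d": 1.0})
        assert se.leibovici_entropy(table).relative == pytest.approx(rel,
                                                                     abs=0.01)

    def test_single_category_entropy_zero(self, unit_square):
        pat = se.PointPattern([(0.1, 0.1), (0.2, 0.2), (0.3, 0.1)],
                              unit_square, ["a", "a", "a"])
        res = se.leibovici_entropy(pat, d=1.0)
        assert res.value == 0.0

    def test_sweep_consistency_and_missing(self, marked_csr_pattern):
        table = se.distance_sweep(marked_csr_pattern, [1e-6, 0.2])
        assert np.isnan(table["relative"].iloc[0])  # below min distance
        single = se.leibovici_entropy(marked_csr_pattern, 0.2)
        assert table["relative"].iloc[1] == pytest.approx(single.relative)

    def test_random_labelling_keeps_relative_high(self, marked_csr_pattern):
        """Independent marks make all couples near-equally likely at every
        distance, so the relative entropy stays near its maximum."""
        ds = se.distance_summaries(marked_csr_pattern)
        deciles = ds.pairwise_quantiles(np.arange(0.1, 0.91, 0.2))
        table = se.distance_sweep(marked_csr_pattern, deciles)
        assert (table["relative"] > 0.95).all()
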