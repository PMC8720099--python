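import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geobiodiv.geodiversity import (Breaks, classify, compound_index,
                                    fisher_breaks, geodiversity_at_plots,
                                    neighborhood_counts, shannon)
from geobiodiv.raster import PlotGeometry, RasterGrid


def exhaustive_min_ssd(values, k):
    """Oracle: minimum within-class SSD over all contiguous partitions of the
    sorted values into at most k groups (brute-force enumeration)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size

    def ssd(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    best = math.inf
    for parts in range(1, min(k, n) + 1):
        for cuts in itertools.combinations(range(1, n), parts - 1):
            edges = (0, *cuts, n)
            total = sum(ssd(v[a:b]) for a, b in zip(edges, edges[1:]))
            best = min(best, total)
    return best


class TestFisherBreaks:
    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 13))
            k = int(rng.integers(1, 6))
            vals = rng.normal(size=n) * rng.uniform(0.1, 50)
            got = fisher_breaks(vals, k).within_class_ssd
            want = exhaustive_min_ssd(vals, k)
            assert got == pytest.approx(want, abs=1e-9)

    def test_three_cluster_example(self):
        b = fisher_breaks([1, 2, 3, 10, 11, 12, 100], 3)
        assert b.boundaries == (3.0, 12.0)
        assert b.within_class_ssd == pytest.approx(4.0)

    def test_identical_values_single_class(self):
        b = fisher_breaks([7.0] * 10, 5)
        assert b.k == 1
        assert b.within_class_ssd == 0.0

    def test_saturated_partition_zero_ssd(self):
        b = fisher_breaks([1.0, 4.0, 9.0, 16.0], 4)
        assert b.k == 4
        assert b.within_class_ssd == pytest.approx(0.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fisher_breaks([], 3)
        with pytest.raises(ValueError):
            fisher_breaks([1.0, np.nan], 3)

    @given(st.lists(st.integers(min_value=-50, max_value=50),
                    min_size=2, max_size=10),
           st.integers(min_value=1, max_value=5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_order_invariance(self, vals, k):
        shuffled = list(reversed(vals))
        a = fisher_breaks(vals, k)
        b = fisher_breaks(shuffled, k)
        assert a.boundaries == b.boundaries
        assert a.within_class_ssd == pytest.approx(b.within_class_ssd)

    def test_affine_rescaling_preserves_partition(self, rng):
        vals = rng.normal(size=30)
        base = classify_labels(vals, 4)
        scaled = classify_labels(3.5 * vals + 11.0, 4)
        np.testing.assert_array_equal(base, scaled)


def classify_labels(vals, k):
    grid = RasterGrid(np.asarray(vals, dtype=float).reshape(1, -1),
                      origin=(0, 1), cell_size=1.0)
    return classify(grid, fisher_breaks(vals, k)).labels


class TestClassify:
    def test_constant_grid_single_label(self):
        grid = RasterGrid(np.full((4, 4), 2.0), origin=(0, 4), cell_size=1.0)
        cl = classify(grid, fisher_breaks(grid.finite_values(), 5))
        assert set(np.unique(cl.labels)) == {1}

    def test_many_values_saturate_five_classes(self, rng):
        vals = rng.normal(size=(25, 40))
        grid = RasterGrid(vals, origin=(0, 25), cell_size=1.0)
        cl = classify(grid, fisher_breaks(grid.finite_values(), 5))
        assert set(np.unique(cl.labels)) == {1, 2, 3, 4, 5}

    def test_boundary_value_falls_in_lower_class(self):
        breaks = Breaks(3, (2.0, 5.0), 0.0)
        grid = RasterGrid(np.array([[1.0, 2.0, 2.0001, 5.0, 5.1]]),
                          origin=(0, 1), cell_size=1.0)
        cl = classify(grid, breaks)
        np.testing.assert_array_equal(cl.labels[0], [1, 1, 2, 2, 3])

    def test_nodata_propagates_as_zero_label(self):
        vals = np.array([[1.0, -9999.0], [2.0, 3.0]])
        grid = RasterGrid(vals, origin=(0, 2), cell_size=1.0)
        cl = classify(grid, fisher_breaks(grid.finite_values(), 2))
        assert cl.labels[0, 1] == 0


class TestNeighborhood:
    def make(self, labels):
        grid = RasterGrid(np.ones_like(labels, dtype=float), origin=(0, 100),
                          cell_size=1.0)
        from geobiodiv.geodiversity import ClassifiedRaster
        return ClassifiedRaster(labels=np.asarray(labels), k=5,
                                source_breaks=Breaks(5, (1, 2, 3, 4), 0.0),
                                grid=grid)

    def test_interior_center_nine_pixels(self):
        cl = self.make(np.ones((5, 5), dtype=int))
        nc = neighborhood_counts(cl, (2, 2))
        assert nc.total == 9
        assert not nc.truncated
        assert nc.counts == {1: 9}

    def test_corner_truncated_to_four(self):
        cl = self.make(np.ones((5, 5), dtype=int))
        nc = neighborhood_counts(cl, (0, 0))
        assert nc.total == 4
        assert nc.truncated

    def test_nodata_cells_dropped(self):
        labels = np.ones((3, 3), dtype=int)
        labels[0, 0] = 0
        nc = neighborhood_counts(self.make(labels), (1, 1))
        assert nc.total == 8
        assert nc.truncated

    def test_strict_mode_raises_on_truncation(self):
        cl = self.make(np.ones((5, 5), dtype=int))
        with pytest.raises(ValueError, match="strict"):
            neighborhood_counts(cl, (0, 0), strict=True)

    def test_center_outside_raises(self):
        cl = self.make(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="outside"):
            neighborhood_counts(cl, (5, 5))


class TestShannon:
    @pytest.mark.parametrize("counts, expected", [
        ((9,), 0.0),
        ((3, 3, 3), math.log(3)),
        ((5, 3, 1), 0.936888307539016),
        ((2, 2, 2, 2, 1), 1.5810937501718238),
        ((5, 4), 0.6869615765973234),
    ])
    def test_closed_forms(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self, rng):
        counts = rng.integers(0, 10, size=8)
        counts[0] = 1
        assert shannon(counts) == pytest.approx(shannon(counts[::-1]))

    def test_bounds(self, rng):
        for _ in range(50):
            c = rng.integers(0, 5, size=5)
            if c.sum() == 0:
                continue
            h = shannon(c)
            assert 0.0 <= h <= math.log(min(5, int(c.sum()))) + 1e-12

    def test_log_base_option(self):
        assert shannon((2, 2), base=2) == pytest.approx(1.0)


class TestCompoundIndex:
    def test_summation(self):
        assert compound_index([0.5, 1.0, 0.25]) == pytest.approx(1.75)
        assert compound_index([0.0, 0.0, 0.0]) == 0.0

    def test_maximum_pattern(self):
        h = shannon((2, 2, 2, 2, 1))
        assert compound_index([h, h, h]) == pytest.approx(3 * 1.5810937501718238)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compound_index([])


class TestGeodiversityAtPlots:
    def grids_and_plot(self, arrays):
        grids = {f"v{i}": RasterGrid(a, origin=(0.0, a.shape[0] * 1.0),
                                     cell_size=1.0)
                 for i, a in enumerate(arrays)}
        some = next(iter(grids.values()))
        x, y = some.cell_center(2, 2)
        return grids, [PlotGeometry("p1", (x, y))]

    def test_constant_rasters_zero_index(self):
        grids, plots = self.grids_and_plot([np.full((5, 5), v) for v in (1., 2., 3.)])
        table = geodiversity_at_plots(grids, plots, k=5)
        assert table.loc[0, "compound_G"] == 0.0

    def test_checkerboard_entropy(self):
        cb = np.indices((5, 5)).sum(axis=0) % 2 * 1.0
        grids, plots = self.grids_and_plot([cb])
        table = geodiversity_at_plots(grids, plots, k=5)
        assert table.loc[0, "H_v0"] == pytest.approx(0.6869615765973234)

    def test_single_class_limit(self, rng):
        grids, plots = self.grids_and_plot([rng.normal(size=(5, 5))])
        table = geodiversity_at_plots(grids, plots, k=1)
        assert table.loc[0, "compound_G"] == 0.0

    def test_compound_bounds_at_default_classes(self, rng):
        arrays = [rng.normal(size=(7, 7)) for _ in range(3)]
        grids, plots = self.grids_and_plot(arrays)
        g = geodiversity_at_plots(grids, plots, k=5).loc[0, "compound_G"]
        assert 0.0 <= g <= 3 * math.log(5) + 1e-12
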