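"""Geodesic distances vs BFS oracle, stem path minimality, radius, and mask."""

import networkx as nx
import numpy as np
import pytest

from maizecfi.errors import SkeletonError
from maizecfi.imaging_io import Calibration, PipelineConfig
from maizecfi.skeleton_analysis import PointsOfInterest, skeletonize_mask
from maizecfi.stem_extraction import (
    build_stem_mask,
    find_top_node,
    geodesic_distance,
    stem_height,
    stem_path,
    stem_radius,
)


def skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """Oracle graph: one node per skeleton pixel, edges between 8-neighbours."""
    g = nx.Graph()
    h, w = skel.shape
    pts = list(zip(*np.nonzero(skel)))
    g.add_nodes_from(pts)
    for r, c in pts:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (dr or dc) and 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                    g.add_edge((r, c), (rr, cc))
    return g


def random_skeleton(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """A random connected skeleton: thinned blob of smoothed noise."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.random((size, size)), 4)
    mask = noise > np.quantile(noise, 0.6)
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 2))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == int(np.argmax(sizes))
    return skeletonize_mask(mask)


class TestFindTopNode:
    def _poi(self, branches, com):
        return PointsOfInterest(
            leaf_tips=[], branch_points=branches, stem_start=None, center_of_mass=com
        )

    def test_nearest_branch_point_wins(self):
        poi = self._poi([(10, 50), (40, 50)], (38.0, 50.0))
        assert find_top_node(poi) == (40, 50)

    def test_single_branch_point_is_returned(self):
        poi = self._poi([(7, 3)], (100.0, 100.0))
        assert find_top_node(poi) == (7, 3)

    def test_tie_breaks_by_smaller_row_then_col(self):
        poi = self._poi([(30, 50), (10, 50)], (20.0, 50.0))
        assert find_top_node(poi) == (10, 50)
        poi = self._poi([(20, 60), (20, 40)], (20.0, 50.0))
        assert find_top_node(poi) == (20, 40)

    def test_no_branch_points_is_an_error(self):
        with pytest.raises(SkeletonError):
            find_top_node(self._poi([], (0.0, 0.0)))


class TestGeodesicDistance:
    def test_straight_line_distances(self):
        skel = np.zeros((5, 30), dtype=bool)
        skel[2, 5:25] = True
        d = geodesic_distance(skel, (2, 5))
        np.testing.assert_array_equal(d[2, 5:25], np.arange(20))
        assert d[2, 5] == 0
        assert np.isinf(d[0, 0])

    def test_source_off_skeleton_is_an_error(self):
        skel = np.zeros((5, 5), dtype=bool)
        skel[2, 2] = True
        with pytest.raises(SkeletonError):
            geodesic_distance(skel, (0, 0))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bfs_oracle_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        skel = random_skeleton(rng)
        pts = list(zip(*np.nonzero(skel)))
        src = pts[rng.integers(len(pts))]
        src = (int(src[0]), int(src[1]))
        d = geodesic_distance(skel, src)
        oracle = nx.single_source_shortest_path_length(skeleton_graph(skel), src)
        for p in pts:
            if p in oracle:
                assert d[p] == oracle[p]
            else:
                assert np.isinf(d[p])


class TestStemPath:
    def test_y_shape_path_uses_the_trunk_only(self):
        skel = np.zeros((30, 30), dtype=bool)
        skel[15:28, 10] = True  # trunk
        for i in range(10):  # two arms from the fork at (15, 10)
            skel[14 - i, 10 + i] = True
            skel[14 - i, 10 - i if 10 - i >= 0 else 0] = True
        path = stem_path(skel, (27, 10), (15, 10))
        assert path[0] == (27, 10)
        assert path[-1] == (15, 10)
        assert all(c == 10 for _, c in path)

    def test_degenerate_single_pixel_path(self):
        skel = np.zeros((5, 5), dtype=bool)
        skel[2, 2] = True
        assert stem_path(skel, (2, 2), (2, 2)) == [(2, 2)]

    @pytest.mark.parametrize("seed", range(8))
    def test_step_count_equals_bfs_distance_and_sum_field_is_minimal(self, seed):
        rng = np.random.default_rng(100 + seed)
        skel = random_skeleton(rng)
        pts = list(zip(*np.nonzero(skel)))
        g = skeleton_graph(skel)
        a = pts[rng.integers(len(pts))]
        comp = nx.node_connected_component(g, a)
        b = list(comp)[rng.integers(len(comp))]
        a, b = (int(a[0]), int(a[1])), (int(b[0]), int(b[1]))
        path = stem_path(skel, a, b)
        assert len(path) - 1 == nx.shortest_path_length(g, a, b)
        # the summed distance field is constant (= global min) along the path
        da = geodesic_distance(skel, a)
        db = geodesic_distance(skel, b)
        total = da + db
        on_path = [total[p] for p in path]
        finite = total[np.asarray(skel) & np.isfinite(total)]
        assert all(v == finite.min() for v in on_path)
        # and the path is simple and 8-connected
        assert len(set(path)) == len(path)
        steps = np.abs(np.diff(np.asarray(path), axis=0))
        assert steps.max() <= 1


class TestStemRadius:
    def test_vertical_bar_half_width(self, config):
        mask = np.zeros((60, 21), dtype=bool)
        mask[5:55, 7:14] = True  # width 7
        path = [(r, 10) for r in range(54, 4, -1)]
        radius, profile, flags = stem_radius(mask, path, config)
        assert radius == pytest.approx(3.5, abs=0.6)
        assert not flags

    def test_short_path_falls_back_with_flag(self, config):
        mask = np.ones((20, 20), dtype=bool)
        path = [(10, c) for c in range(5, 10)]
        _, _, flags = stem_radius(mask, path, config)
        assert "short_path_unfiltered_radius" in flags

    def test_width_one_structures_have_tiny_radius(self, config):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 20] = True
        path = [(r, 20) for r in range(34, 4, -1)]
        radius, _, _ = stem_radius(mask, path, config)
        assert radius <= 1.0


class TestBuildStemMask:
    def test_bar_is_covered_at_half_width_radius(self):
        mask = np.zeros((60, 21), dtype=bool)
        mask[5:55, 7:14] = True
        path = [(r, 10) for r in range(54, 4, -1)]
        stem = build_stem_mask(mask, path, 3.5)
        assert stem.sum() >= 0.95 * mask.sum()
        assert not (stem & ~mask).any()  # subset of the plant mask

    def test_tiny_radius_reduces_to_the_path(self):
        mask = np.ones((30, 30), dtype=bool)
        path = [(r, 15) for r in range(25, 5, -1)]
        stem = build_stem_mask(mask, path, 0.5)
        assert stem.sum() <= 3 * len(path)

    def test_pixel_count_monotone_in_radius(self, rng):
        mask = rng.random((50, 50)) < 0.7
        path = [(r, 25) for r in range(45, 5, -1)]
        mask[np.asarray([p[0] for p in path]), 25] = True
        counts = [build_stem_mask(mask, path, r).sum() for r in (1, 2, 4, 8, 16)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestStemHeight:
    def test_vertical_segment_arithmetic(self):
        cal = Calibration(cm_per_px=0.1)
        path = [(199, 50), (99, 50)]
        assert stem_height(path, cal) == pytest.approx(10.0)

    def test_degenerate_zero_height(self):
        cal = Calibration(cm_per_px=0.1)
        assert stem_height([(10, 10)], cal) == 0.0
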