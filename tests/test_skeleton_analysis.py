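"""Skeleton topology: thinning, spur pruning, and landmark classification."""

import numpy as np
import pytest

from maizecfi.errors import SkeletonError
from maizecfi.skeleton_analysis import (
    branch_point_clusters,
    find_landmarks,
    half_area_column,
    neighbor_counts,
    skeleton_endpoints,
    skeletonize_mask,
    trim_spurs,
)
from maizecfi.synthetic_plants import LeafSpec, SyntheticPlantSpec, render_plant


def brute_force_degrees(skel: np.ndarray):
    """Oracle: per-pixel neighbour count by explicit loops."""
    h, w = skel.shape
    endpoints, branches = [], []
    for r in range(h):
        for c in range(w):
            if not skel[r, c]:
                continue
            deg = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr or dc) and 0 <= r + dr < h and 0 <= c + dc < w:
                        deg += bool(skel[r + dr, c + dc])
            if deg <= 1:
                endpoints.append((r, c))
            elif deg >= 3:
                branches.append((r, c))
    return endpoints, branches


def _plus_sign(size=61, arm=25, thick=5):
    mask = np.zeros((size, size), dtype=bool)
    mid = size // 2
    mask[mid - thick // 2 : mid + thick // 2 + 1, mid - arm : mid + arm + 1] = True
    mask[mid - arm : mid + arm + 1, mid - thick // 2 : mid + thick // 2 + 1] = True
    return mask


class TestSkeletonize:
    def test_bar_reduces_to_a_line(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[8:11, 5:55] = True
        skel = skeletonize_mask(mask)
        rows = np.nonzero(skel)[0]
        assert len(np.unique(rows)) <= 3  # essentially one horizontal line
        assert skel.sum() >= 45

    def test_plus_sign_topology(self):
        skel = trim_spurs(skeletonize_mask(_plus_sign()), 3)
        eps = skeleton_endpoints(skel)
        clusters = branch_point_clusters(skel)
        assert len(eps) == 4
        assert len(clusters) == 1

    def test_empty_mask_is_an_error(self):
        with pytest.raises(SkeletonError):
            skeletonize_mask(np.zeros((10, 10), dtype=bool))

    def test_skeleton_is_single_pixel_wide(self, nonoverlap, config):
        """No 2x2 all-foreground block anywhere in a trimmed plant skeleton."""
        from maizecfi.segmentation import segment_plant

        _, img, _, _ = nonoverlap[0]
        skel = trim_spurs(skeletonize_mask(segment_plant(img, config)), config.spur_length_px)
        two_by_two = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        assert not two_by_two.any()

    def test_degree_classification_matches_brute_force(self, config):
        from maizecfi.segmentation import segment_plant

        image, _ = render_plant(SyntheticPlantSpec(seed=21))
        skel = trim_spurs(skeletonize_mask(segment_plant(image, config)), 10)
        eps_oracle, branches_oracle = brute_force_degrees(skel)
        assert skeleton_endpoints(skel) == eps_oracle
        counts = neighbor_counts(skel)
        got_branch_px = sorted(zip(*np.nonzero(counts >= 3)))
        assert [(int(r), int(c)) for r, c in got_branch_px] == branches_oracle


class TestTrimSpurs:
    def test_side_twig_is_pruned(self):
        skel = np.zeros((20, 120), dtype=bool)
        skel[10, 5:105] = True
        skel[7:10, 50] = True  # 3-px twig
        trimmed = trim_spurs(skel, 10)
        assert not trimmed[8, 50]
        assert len(skeleton_endpoints(trimmed)) == 2

    def test_zero_length_is_identity(self):
        skel = np.zeros((20, 40), dtype=bool)
        skel[10, 5:35] = True
        skel[7:10, 20] = True
        np.testing.assert_array_equal(trim_spurs(skel, 0), skel)

    def test_no_short_terminal_branch_survives(self, nonoverlap, config):
        """Re-scan property: after trimming with s, every endpoint's branch
        has geodesic length >= s (or ends at another endpoint)."""
        from maizecfi.segmentation import segment_plant
        from maizecfi.skeleton_analysis import _walk_from_endpoint

        _, img, _, _ = nonoverlap[1]
        skel = trim_spurs(skeletonize_mask(segment_plant(img, config)), config.spur_length_px)
        counts = neighbor_counts(skel)
        for ep in skeleton_endpoints(skel):
            branch, hit = _walk_from_endpoint(skel, counts, ep, config.spur_length_px)
            assert not (hit and len(branch) < config.spur_length_px)

    def test_simple_arc_is_never_pruned_away(self):
        skel = np.zeros((10, 10), dtype=bool)
        skel[5, 2:8] = True
        trimmed = trim_spurs(skel, 50)
        assert trimmed.sum() == skel.sum()


class TestLandmarks:
    def test_vertical_line_has_bottom_stem_start_and_one_tip(self, config):
        mask = np.zeros((60, 41), dtype=bool)
        mask[5:55, 18:23] = True
        skel = np.zeros_like(mask)
        skel[5:55, 20] = True
        poi = find_landmarks(skel, mask, config)
        assert poi.stem_start == (54, 20)
        assert poi.leaf_tips == [(5, 20)]
        assert poi.branch_points == []
        assert poi.center_of_mass[1] == pytest.approx(20.0)

    def test_plus_sign_gives_three_tips(self, config):
        mask = _plus_sign()
        skel = trim_spurs(skeletonize_mask(mask), 3)
        poi = find_landmarks(skel, mask, config)
        assert poi.stem_start is not None
        assert poi.stem_start[0] == max(p[0] for p in skeleton_endpoints(skel))
        assert len(poi.leaf_tips) == 3

    def test_half_area_column_of_symmetric_mask_is_central(self):
        mask = np.zeros((20, 41), dtype=bool)
        mask[:, 10:31] = True
        assert abs(half_area_column(mask) - 20) <= 1

    def test_drooping_tip_below_stem_base_stays_a_leaf_tip(self, config):
        """A leaf tip lower than the stem base but off the midline must be
        classified as a tip, not as the stem start."""
        from maizecfi.segmentation import segment_plant

        droop = LeafSpec(
            attach_frac=0.4, length_px=400.0, max_width_px=14.0,
            tip_angle_deg=125.0, side="right", curvature=0.03,
        )
        top = LeafSpec(
            attach_frac=1.0, length_px=300.0, max_width_px=14.0,
            tip_angle_deg=70.0, side="left", curvature=0.02,
        )
        spec = SyntheticPlantSpec(stem_height_px=320, leaves=(droop, top), seed=4)
        image, truth = render_plant(spec)
        mask = segment_plant(image, config)
        skel = trim_spurs(skeletonize_mask(mask), config.spur_length_px)
        poi = find_landmarks(skel, mask, config)
        droop_tip_row = truth.leaf_tips[0][0]
        assert droop_tip_row > spec.stem_base_row - 20  # genuinely droops low
        assert poi.stem_start is not None
        assert abs(poi.stem_start[1] - spec.stem_col) < 20  # on the midline
        assert any(abs(t[0] - droop_tip_row) < 12 for t in poi.leaf_tips)

    def test_tip_count_is_endpoints_minus_stem_start(self, nonoverlap, config):
        from maizecfi.segmentation import segment_plant

        _, img, _, _ = nonoverlap[2]
        mask = segment_plant(img, config)
        skel = trim_spurs(skeletonize_mask(mask), config.spur_length_px)
        poi = find_landmarks(skel, mask, config)
        assert len(poi.leaf_tips) + 1 == len(skeleton_endpoints(skel))
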