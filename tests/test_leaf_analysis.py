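"""Leaf separation, whorl removal, ranking, areas, and tip angles."""

import numpy as np
import pytest

from maizecfi.errors import NoPlantError
from maizecfi.imaging_io import Calibration
from maizecfi.leaf_analysis import (
    LeafTraits,
    leaf_angle,
    leaf_area,
    rank_leaves,
    remove_whorl,
    separate_leaves,
)


def _blob_at(shape, r0, r1, c0, c1):
    b = np.zeros(shape, dtype=bool)
    b[r0:r1, c0:c1] = True
    return b


class TestSeparateLeaves:
    def test_plus_sign_minus_bar_leaves_two_arms(self, config):
        plant = np.zeros((100, 100), dtype=bool)
        plant[20:80, 40:60] = True  # vertical bar
        plant[40:60, 10:90] = True  # horizontal bar
        stem = np.zeros_like(plant)
        stem[20:80, 40:60] = True
        blobs, discarded, n_disc = separate_leaves(plant, stem, config)
        assert len(blobs) == 2
        assert discarded == 0 and n_disc == 0
        total = sum(int(b.sum()) for b in blobs)
        assert total == int((plant & ~stem).sum())

    def test_stem_covers_plant_reports_no_leaves(self, config):
        plant = _blob_at((50, 50), 10, 40, 20, 30)
        with pytest.raises(NoPlantError):
            separate_leaves(plant, plant, config)

    def test_fragments_below_threshold_are_counted_not_kept(self, config):
        plant = np.zeros((100, 100), dtype=bool)
        plant[10:90, 45:55] = True
        plant[20:30, 60:75] = True  # 150-px leaf
        plant[50:53, 56:60] = True  # 12-px fragment
        stem = _blob_at((100, 100), 10, 90, 45, 55)
        blobs, discarded, n_disc = separate_leaves(plant, stem, config)
        assert len(blobs) == 1
        assert discarded == 12 and n_disc == 1


class TestRemoveWhorl:
    def test_highest_blob_is_the_whorl(self):
        shape = (200, 100)
        low = _blob_at(shape, 170, 190, 10, 30)
        mid = _blob_at(shape, 90, 110, 10, 30)
        high = _blob_at(shape, 10, 30, 10, 30)
        whorl, rest = remove_whorl([low, mid, high])
        assert whorl[20, 20]
        assert len(rest) == 2

    def test_single_blob_is_the_whorl_and_no_leaves_remain(self):
        only = _blob_at((50, 50), 10, 20, 10, 20)
        whorl, rest = remove_whorl([only])
        assert whorl is only
        assert rest == []


class TestRankLeaves:
    def test_bottom_up_ranking(self, cal):
        shape = (200, 100)
        blobs = [
            _blob_at(shape, 10, 30, 10, 30),  # highest
            _blob_at(shape, 170, 190, 10, 30),  # lowest
            _blob_at(shape, 90, 110, 10, 30),
        ]
        ranked = rank_leaves(blobs, cal)
        assert [l.rank for l in ranked] == [1, 2, 3]
        rows = [l.center_of_mass[0] for l in ranked]
        assert rows == sorted(rows, reverse=True)

    def test_single_blob_is_rank_one(self, cal):
        ranked = rank_leaves([_blob_at((50, 50), 10, 20, 10, 20)], cal)
        assert len(ranked) == 1 and ranked[0].rank == 1


class TestLeafArea:
    def test_pixel_count_times_scale_squared(self):
        blob = _blob_at((50, 50), 10, 20, 10, 20)  # 100 px
        assert leaf_area(blob, Calibration(cm_per_px=0.1)) == pytest.approx(1.0)
        one = np.zeros((50, 50), dtype=bool)
        one[5, 5] = True
        assert leaf_area(one, Calibration(cm_per_px=0.05)) == pytest.approx(0.0025)

    def test_exact_on_rendered_leaf_labels(self, nonoverlap, cal):
        spec, _, truth, _ = nonoverlap[0]
        for lab, area in zip(truth.leaf_labels, truth.leaf_areas_cm2):
            blob = truth.label_image == lab
            assert leaf_area(blob, cal) == pytest.approx(area)


class TestLeafAngle:
    def _measure(self, tip, attachment_col=20):
        """Vertical stem path through col 20; blob = 3x3 square at the tip."""
        shape = (100, 60)
        path = [(r, attachment_col) for r in range(90, 10, -1)]
        blob = np.zeros(shape, dtype=bool)
        blob[tip[0] - 1 : tip[0] + 2, tip[1] - 1 : tip[1] + 2] = True
        leaf = LeafTraits(
            rank=1, blob_mask=blob, area_cm2=1.0, center_of_mass=(float(tip[0]), float(tip[1]))
        )
        return leaf_angle(leaf, path, [tip])

    def test_tip_straight_above_attachment_is_zero_degrees(self):
        leaf = self._measure((15, 20))
        assert leaf.angle_deg == pytest.approx(0.0, abs=3.0)

    def test_horizontal_tip_is_ninety_degrees(self):
        leaf = self._measure((50, 45))
        assert leaf.angle_deg == pytest.approx(90.0, abs=3.0)

    def test_drooping_tip_exceeds_ninety_degrees(self):
        # tip below the bottom of the stem path: the attachment is the path
        # end, and the tip hangs below it
        leaf = self._measure((96, 40))
        assert leaf.angle_deg is not None and leaf.angle_deg > 90.0

    def test_blob_without_a_unique_tip_is_flagged(self):
        shape = (100, 60)
        path = [(r, 20) for r in range(90, 10, -1)]
        blob = _blob_at(shape, 40, 60, 30, 50)
        leaf = LeafTraits(rank=1, blob_mask=blob, area_cm2=1.0, center_of_mass=(50.0, 40.0))
        out = leaf_angle(leaf, path, [(50, 40), (55, 45)])
        assert out.angle_deg is None
        assert "occluded_or_merged" in out.flags

    def test_angle_is_mirror_equivariant(self, nonoverlap, config):
        """Flipping the image left-right preserves every leaf angle."""
        from maizecfi.pipeline import analyze_image
        from maizecfi.plant_traits import mirror_image

        _, img, _, rec = nonoverlap[3]
        mirrored = analyze_image(mirror_image(img), config)
        a1 = sorted(l.angle_deg for l in rec.leafset.leaves if l.angle_deg is not None)
        a2 = sorted(l.angle_deg for l in mirrored.leafset.leaves if l.angle_deg is not None)
        assert len(a1) == len(a2)
        np.testing.assert_allclose(a1, a2, atol=1.0)


def test_pixel_conservation_on_rendered_plant(nonoverlap):
    """|plant| = |stem| + |whorl| + sum(|blobs|) + |discarded|, exactly."""
    from maizecfi.pipeline import check_pixel_conservation
    from maizecfi.segmentation import segment_plant

    for _, img, _, rec in nonoverlap[:4]:
        mask = segment_plant(img)
        assert check_pixel_conservation(rec, mask)
        assert "pixel_conservation_violation" not in rec.flags
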