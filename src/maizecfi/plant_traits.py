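"""Whole-plant traits, top-view orientation, and the per-plant record.

Whole-plant height and width are the sides of the axis-aligned bounding box of
the plant mask (inclusive pixel extents), and the side-projected area is the
mask pixel count — all scaled to physical units by the calibration.

Top-view orientation supports the imaging protocol in which the rotation table
turns each plant so its broadest side faces the side camera: the orientation
is the angle of the longest axis of the top-view silhouette (its farthest
pixel pair, always realised on the convex hull) to the horizontal x-axis.
Because maize is roughly bilaterally symmetric, a side view and its left-right
mirror are interchangeable; the pipeline's traits are mirror-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import InputError
from .imaging_io import Calibration, GrayImage
from .leaf_analysis import LeafSet
from .stem_extraction import StemTraits

__all__ = [
    "PlantRecord",
    "whole_plant_traits",
    "top_view_orientation",
    "mirror_image",
]


@dataclass
class PlantRecord:
    """All traits extracted from one side-view image.

    ``stem`` and ``leafset`` are ``None`` when the corresponding stage could
    not run (e.g. no branch point -> no top node); the plant-level traits are
    still reported and the reason is recorded in ``flags``.
    """

    plant_id: str
    image_path: str = ""
    height_cm: float = float("nan")
    width_cm: float = float("nan")
    projected_area_cm2: float = float("nan")
    stem: StemTraits | None = None
    leafset: LeafSet | None = None
    flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        """Plant-level CSV row."""
        stem = self.stem
        return {
            "plant_id": self.plant_id,
            "image_path": self.image_path,
            "height_cm": self.height_cm,
            "width_cm": self.width_cm,
            "projected_area_cm2": self.projected_area_cm2,
            "stem_height_cm": stem.stem_height_cm if stem else float("nan"),
            "vertical_stem_height_cm": stem.vertical_stem_height_cm if stem else float("nan"),
            "stem_path_length_cm": stem.stem_path_length_cm if stem else float("nan"),
            "stem_diameter_cm": stem.diameter_cm if stem else float("nan"),
            "n_leaves": self.leafset.n_leaves if self.leafset else 0,
            "flags": ";".join(self.flags),
        }

    def leaf_rows(self) -> list[dict]:
        """Per-leaf long-format CSV rows."""
        if self.leafset is None:
            return []
        return [
            {
                "plant_id": self.plant_id,
                "leaf_rank": leaf.rank,
                "leaf_area_cm2": leaf.area_cm2,
                "leaf_angle_deg": leaf.angle_deg if leaf.angle_deg is not None else float("nan"),
            }
            for leaf in self.leafset.leaves
        ]


def whole_plant_traits(mask: np.ndarray, cal: Calibration) -> tuple[float, float, float]:
    """Height, width, and side-projected area of the plant mask.

    Height and width are the inclusive bounding-box extents
    (``max - min + 1`` pixels); area is the foreground pixel count.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise InputError("empty mask has no extents")
    height_cm = cal.length_cm(int(rows.max() - rows.min() + 1))
    width_cm = cal.length_cm(int(cols.max() - cols.min() + 1))
    area_cm2 = cal.area_cm2(int(rows.size))
    return height_cm, width_cm, area_cm2


def _pair_angle_deg(p: np.ndarray, q: np.ndarray) -> float:
    """Angle of segment pq to the horizontal x-axis, folded into [0, 180)."""
    dy = -(float(q[0]) - float(p[0]))  # y increases upward
    dx = float(q[1]) - float(p[1])
    ang = np.degrees(np.arctan2(dy, dx)) % 180.0
    return float(ang)


def top_view_orientation(top_mask: np.ndarray) -> float:
    """Orientation of the longest axis of a top-view silhouette, in [0, 180).

    The longest axis is the farthest pair of foreground pixels; since the
    farthest pair of any point set is attained on its convex hull, only hull
    vertices are searched (a speed-up, not an approximation).  Distance ties
    break toward the smaller angle.  Degenerate masks (all pixels collinear or
    fewer than 3) are handled by direct pairwise search; a single pixel has
    orientation 0.
    """
    top_mask = np.asarray(top_mask, dtype=bool)
    pts = np.argwhere(top_mask)
    if pts.shape[0] == 0:
        raise InputError("empty top-view mask")
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 3:
        try:
            hull = ConvexHull(pts.astype(float))
            pts = pts[hull.vertices]
        except QhullError:
            pass  # collinear: brute-force over the (few) original points
    best = (-1.0, 181.0)  # (squared distance, angle)
    for i in range(len(pts)):
        diff = pts[i + 1 :] - pts[i]
        if len(diff) == 0:
            continue
        d2 = (diff**2).sum(axis=1)
        for j in np.nonzero(d2 >= best[0])[0]:
            ang = _pair_angle_deg(pts[i], pts[i + 1 + j])
            cand = (float(d2[j]), ang)
            if cand[0] > best[0] or (cand[0] == best[0] and ang < best[1]):
                best = cand
    return best[1]


def mirror_image(image: GrayImage) -> GrayImage:
    """Left-right flip of the image (the 180-degree-rotated view of a plant).

    Running the full pipeline on the mirrored image yields the same traits
    (heights, areas, leaf count, angles) within discretisation error.
    """
    return GrayImage(pixels=np.fliplr(image.pixels), bit_depth=image.bit_depth)
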