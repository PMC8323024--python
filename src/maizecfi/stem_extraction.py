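"""Stem segmentation: top node, geodesic stem path, radius, mask, and height.

The stem is defined from the soil line up to the node bearing the youngest
fully expanded leaf (the "top node", following the Leaf Collar convention for
staging maize).  The top node is taken as the skeleton branch point closest to
the skeleton's centre of mass — in vegetative-stage maize the whorl and the
upper leaves concentrate skeletal mass near the top of the stalk, which pulls
the centre of mass toward the youngest node.

The stem path is recovered on the skeleton graph: summing the geodesic
distance fields from the stem start and from the top node yields a field whose
regional minimum is exactly the set of pixels on shortest start-to-top paths;
the extracted path is one such shortest path.  The local stem radius is read
off the Euclidean distance transform of the plant mask along this path.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import SkeletonError
from .imaging_io import Calibration, PipelineConfig
from .skeleton_analysis import PointsOfInterest

__all__ = [
    "StemTraits",
    "find_top_node",
    "geodesic_distance",
    "stem_path",
    "stem_radius",
    "build_stem_mask",
    "stem_height",
    "extract_stem",
]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class StemTraits:
    """Measurements of the segmented stem.

    ``path`` is an ordered, 8-connected, simple pixel chain from the stem start
    to the top node.  ``stem_height_cm`` is the straight-line start-to-top
    distance; the vertical drop and the path arc length are exported alongside
    because the field convention (Euclidean vs vertical) is ambiguous.
    ``diameter_cm`` is ``2 * radius_px * cm_per_px``.
    """

    path: list[tuple[int, int]]
    stem_height_cm: float
    vertical_stem_height_cm: float
    stem_path_length_cm: float
    radius_px: float
    diameter_cm: float
    stem_mask: np.ndarray
    flags: list[str] = field(default_factory=list)


def find_top_node(poi: PointsOfInterest) -> tuple[int, int]:
    """Branch point closest (Euclidean) to the skeleton's centre of mass.

    Ties are broken by smaller row, then smaller column.  Raises
    :class:`SkeletonError` when there are no branch points (a plant with no
    fully expanded leaf has no top node; stem traits are then absent).
    """
    if not poi.branch_points:
        raise SkeletonError("no branch points: top node undefined")
    cr, cc = poi.center_of_mass
    return min(
        poi.branch_points,
        key=lambda p: ((p[0] - cr) ** 2 + (p[1] - cc) ** 2, p[0], p[1]),
    )


def geodesic_distance(skel: np.ndarray, source: tuple[int, int]) -> np.ndarray:
    """Geodesic (on-skeleton) distance from ``source`` to every skeleton pixel.

    Distances are minimal counts of 8-connected steps along skeleton pixels
    (unit cost per step, chessboard metric).  Non-skeleton and unreachable
    pixels are ``inf``.
    """
    skel = np.asarray(skel, dtype=bool)
    r0, c0 = int(source[0]), int(source[1])
    if not skel[r0, c0]:
        raise SkeletonError(f"source {source} is not on the skeleton")
    h, w = skel.shape
    dist = np.full((h, w), np.inf)
    dist[r0, c0] = 0.0
    queue: deque[tuple[int, int]] = deque([(r0, c0)])
    while queue:
        r, c = queue.popleft()
        d = dist[r, c] + 1.0
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel[rr, cc] and d < dist[rr, cc]:
                dist[rr, cc] = d
                queue.append((rr, cc))
    return dist


def stem_path(
    skel: np.ndarray, start: tuple[int, int], top: tuple[int, int]
) -> list[tuple[int, int]]:
    """Shortest skeleton path from ``start`` to ``top``, ordered start-first.

    The path realises the regional minimum of the summed distance field
    ``d(., start) + d(., top)``: along the returned pixels the sum is constant
    and equal to its global minimum over the skeleton, and the step count
    equals the geodesic start-to-top distance.  Ambiguities between equally
    short paths are resolved deterministically (smaller row, then column).
    """
    d_start = geodesic_distance(skel, start)
    if not np.isfinite(d_start[top[0], top[1]]):
        raise SkeletonError("start and top node lie on different skeleton components")
    h, w = skel.shape
    path = [(int(top[0]), int(top[1]))]
    cur = path[0]
    while d_start[cur] > 0:
        r, c = cur
        target = d_start[r, c] - 1.0
        step = None
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and d_start[rr, cc] == target:
                if step is None or (rr, cc) < step:
                    step = (rr, cc)
        cur = step
        path.append(cur)
    path.reverse()
    return path


def stem_radius(
    mask: np.ndarray, path: list[tuple[int, int]], config: PipelineConfig | None = None
) -> tuple[float, np.ndarray, list[str]]:
    """Representative stem radius from the mask's distance transform.

    The Euclidean distance transform of the plant mask is sampled along the
    stem path (the value at a medial pixel is the local half-width), the
    profile is smoothed with a 1-D median filter of width ``median_window``
    to suppress bulges at leaf junctions, and the representative radius is the
    median of the filtered profile.

    Returns ``(radius_px, filtered_profile, flags)``; paths shorter than the
    filter window fall back to the unfiltered median and are flagged.
    """
    if config is None:
        config = PipelineConfig()
    mask = np.asarray(mask, dtype=bool)
    edt = ndimage.distance_transform_edt(mask)
    profile = np.array([edt[r, c] for r, c in path], dtype=float)
    flags: list[str] = []
    if len(profile) < config.median_window:
        flags.append("short_path_unfiltered_radius")
        filtered = profile
    else:
        filtered = ndimage.median_filter(profile, size=config.median_window, mode="nearest")
    return float(np.median(filtered)), filtered, flags


def build_stem_mask(
    mask: np.ndarray, path: list[tuple[int, int]], radius_px: float
) -> np.ndarray:
    """Plant-mask pixels within ``radius_px`` of the stem path.

    The result is a subset of the plant mask and is connected (the component
    containing the path is kept should discretisation ever detach a sliver).
    The pixel count is non-decreasing in ``radius_px``.
    """
    mask = np.asarray(mask, dtype=bool)
    path_mask = np.zeros_like(mask)
    rows, cols = zip(*path)
    path_mask[list(rows), list(cols)] = True
    dist_to_path = ndimage.distance_transform_edt(~path_mask)
    stem = mask & (dist_to_path <= radius_px)
    labels, n = ndimage.label(stem, structure=ndimage.generate_binary_structure(2, 2))
    if n > 1:
        keep = labels[path[0][0], path[0][1]]
        stem = labels == keep
    return stem


def stem_height(path: list[tuple[int, int]], cal: Calibration) -> float:
    """Straight-line distance between the stem start and the top node, in cm."""
    if not path:
        raise SkeletonError("empty stem path")
    (r0, c0), (r1, c1) = path[0], path[-1]
    return cal.length_cm(float(np.hypot(r1 - r0, c1 - c0)))


def _arc_length_px(path: list[tuple[int, int]]) -> float:
    if len(path) < 2:
        return 0.0
    pts = np.asarray(path, dtype=float)
    return float(np.sum(np.hypot(*(np.diff(pts, axis=0).T))))


def extract_stem(
    skel: np.ndarray,
    mask: np.ndarray,
    poi: PointsOfInterest,
    config: PipelineConfig | None = None,
) -> StemTraits:
    """Run the full stem stage: top node, path, radius, mask, heights."""
    if config is None:
        config = PipelineConfig()
    if poi.stem_start is None:
        raise SkeletonError("stem start not found")
    top = find_top_node(poi)
    poi.top_node = top
    path = stem_path(skel, poi.stem_start, top)
    radius_px, _, flags = stem_radius(mask, path, config)
    smask = build_stem_mask(mask, path, radius_px)
    cal = config.calibration
    return StemTraits(
        path=path,
        stem_height_cm=stem_height(path, cal),
        vertical_stem_height_cm=cal.length_cm(abs(path[-1][0] - path[0][0])),
        stem_path_length_cm=cal.length_cm(_arc_length_px(path)),
        radius_px=radius_px,
        diameter_cm=2.0 * radius_px * cal.cm_per_px,
        stem_mask=smask,
        flags=flags,
    )
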