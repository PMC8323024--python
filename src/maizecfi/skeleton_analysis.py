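"""Skeletonization, spur pruning, and topological landmark classification.

The cleaned plant mask is thinned to a one-pixel-wide skeleton.  Short terminal
branches ("spurs") produced by thinning artifacts are pruned.  Skeleton pixels
are then classified by their 8-neighbourhood degree: endpoints (1 neighbour)
and branch points (>= 3 neighbours).  The endpoint at the bottom of the image
that sits on the plant's vertical midline is the stem start point; every other
endpoint is a leaf tip — including tips that droop below the stem base, which
fail the midline test and are therefore kept as leaf tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import SkeletonError
from .imaging_io import PipelineConfig

__all__ = [
    "PointsOfInterest",
    "skeletonize_mask",
    "trim_spurs",
    "neighbor_counts",
    "skeleton_endpoints",
    "branch_point_clusters",
    "half_area_column",
    "find_landmarks",
]

_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class PointsOfInterest:
    """Classified skeleton landmarks.

    ``stem_start`` is the qualifying endpoint with the maximal row (lowest in
    the image); ``center_of_mass`` is the mean (row, col) over skeleton pixels;
    ``top_node`` is filled in later by the stem-extraction stage and is always
    a member of ``branch_points``.
    """

    leaf_tips: list[tuple[int, int]]
    branch_points: list[tuple[int, int]]
    stem_start: tuple[int, int] | None
    center_of_mass: tuple[float, float]
    top_node: tuple[int, int] | None = None
    flags: list[str] = field(default_factory=list)


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide, topology-preserving medial skeleton of a binary mask.

    The medial axis is used as the base skeleton because it extends close to
    the extremities of the shape (a plain thinning retracts endpoints by
    about half the local width, which would bias the stem start point well
    above the soil line); a thinning pass afterwards reduces any remaining
    2-pixel-wide diagonal runs to single-pixel width without retracting
    endpoints.  The mask must be a single connected component (guaranteed by
    :func:`~maizecfi.segmentation.clean_mask`).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SkeletonError("cannot skeletonize an empty mask")
    # medial_axis breaks skeletonization ties in random order unless the rng
    # is pinned; the pipeline must be deterministic
    skel = morphology.skeletonize(morphology.medial_axis(mask, rng=0))
    return _remove_redundant_corners(skel)


def _remove_redundant_corners(skel: np.ndarray) -> np.ndarray:
    """Drop degree-2 pixels whose two neighbours are themselves adjacent.

    Such pixels are topologically redundant (their removal leaves the
    neighbours directly connected).  Thinning occasionally leaves them as
    3-pixel triangles at blunt branch ends — where they would mask the
    endpoint — and as staircase corners.  Scanning is row-major and repeats
    until stable, so the result is deterministic.
    """
    skel = skel.copy()
    h, w = skel.shape
    changed = True
    while changed:
        changed = False
        counts = neighbor_counts(skel)
        rows, cols = np.nonzero(skel & (counts == 2))
        for r, c in zip(rows, cols):
            if not skel[r, c]:
                continue
            nbrs = [
                (r + dr, c + dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr or dc)
                and 0 <= r + dr < h
                and 0 <= c + dc < w
                and skel[r + dr, c + dc]
            ]
            if len(nbrs) == 2:
                (r1, c1), (r2, c2) = nbrs
                if abs(r1 - r2) <= 1 and abs(c1 - c2) <= 1:
                    skel[r, c] = False
                    changed = True
    return skel


def neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """Number of 8-connected skeleton neighbours of every skeleton pixel (0 elsewhere)."""
    skel = np.asarray(skel, dtype=bool)
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    counts = ndimage.convolve(skel.astype(int), kernel, mode="constant", cval=0)
    counts[~skel] = 0
    return counts


def skeleton_endpoints(skel: np.ndarray) -> list[tuple[int, int]]:
    """Skeleton pixels with exactly one neighbour, in row-major order.

    A single isolated pixel (degree 0) is also treated as an endpoint.
    """
    counts = neighbor_counts(skel)
    skel = np.asarray(skel, dtype=bool)
    rows, cols = np.nonzero(skel & ((counts == 1) | (counts == 0)))
    return [(int(r), int(c)) for r, c in zip(rows, cols)]


def branch_point_clusters(skel: np.ndarray) -> list[tuple[int, int]]:
    """Representative branch points, one per cluster of adjacent high-degree pixels.

    Thinning often yields several mutually adjacent pixels of degree >= 3 at a
    single anatomical junction; these are merged by 8-connectivity and the
    skeleton pixel nearest the cluster centroid is returned as the
    representative, so each junction maps to exactly one marker.
    """
    counts = neighbor_counts(skel)
    branch_mask = counts >= 3
    labels, n = ndimage.label(branch_mask, structure=_EIGHT)
    reps: list[tuple[int, int]] = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(labels == i)
        cr, cc = rows.mean(), cols.mean()
        k = int(np.argmin((rows - cr) ** 2 + (cols - cc) ** 2))
        reps.append((int(rows[k]), int(cols[k])))
    reps.sort()
    return reps


def _walk_from_endpoint(
    skel: np.ndarray, counts: np.ndarray, endpoint: tuple[int, int], max_len: int
) -> tuple[list[tuple[int, int]], bool]:
    """Follow the branch from ``endpoint`` until a branch point or ``max_len`` steps.

    Returns the visited simple-branch pixels (branch point excluded) and whether
    a branch point terminated the walk.
    """
    h, w = skel.shape
    path = [endpoint]
    visited = {endpoint}
    cur = endpoint
    while len(path) <= max_len:
        r, c = cur
        nxt = None
        hit_branch = False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and skel[rr, cc] and (rr, cc) not in visited:
                    if counts[rr, cc] >= 3:
                        hit_branch = True
                    elif nxt is None:
                        nxt = (rr, cc)
        if hit_branch:
            return path, True
        if nxt is None:  # isolated arc: other endpoint reached
            return path, False
        cur = nxt
        visited.add(cur)
        path.append(cur)
    return path, False


def trim_spurs(skel: np.ndarray, spur_length_px: int) -> np.ndarray:
    """Iteratively prune terminal branches shorter than ``spur_length_px``.

    A terminal branch runs from an endpoint to the nearest branch point; its
    geodesic length is its step count.  Branches of length ``< spur_length_px``
    are removed (the branch point itself is kept), and the scan repeats until
    no short spur remains.  Connectivity is preserved; with
    ``spur_length_px == 0`` the input is returned unchanged.  A skeleton with
    no branch points (a simple arc) is never pruned away.
    """
    skel = np.asarray(skel, dtype=bool).copy()
    if spur_length_px <= 0:
        return skel
    while True:
        counts = neighbor_counts(skel)
        removed_any = False
        for ep in skeleton_endpoints(skel):
            if not skel[ep]:  # may already be gone this round
                continue
            branch, hit_branch_point = _walk_from_endpoint(skel, counts, ep, spur_length_px)
            # branch length in steps = len(branch) when it ends at a branch point
            if hit_branch_point and len(branch) < spur_length_px:
                for r, c in branch:
                    skel[r, c] = False
                removed_any = True
        # pruning both prongs of a tiny tip fork can leave a blunt 3-pixel
        # cycle with no degree-1 pixel; re-thinning plus redundant-corner
        # removal collapses it back to a proper endpoint
        rethinned = _remove_redundant_corners(morphology.skeletonize(skel))
        changed = removed_any or bool(np.any(rethinned != skel))
        skel = rethinned
        if not changed:
            return skel


def half_area_column(mask: np.ndarray) -> int:
    """Column at which the cumulative column-wise mask area first reaches 50%."""
    col_area = np.asarray(mask, dtype=bool).sum(axis=0)
    total = col_area.sum()
    if total == 0:
        raise SkeletonError("empty mask has no half-area column")
    return int(np.searchsorted(np.cumsum(col_area), total / 2.0))


def find_landmarks(
    skel: np.ndarray, mask: np.ndarray, config: PipelineConfig | None = None
) -> PointsOfInterest:
    """Classify skeleton endpoints and branch points into plant landmarks.

    The stem start is the endpoint with the maximal row whose column lies
    within ``midline_tolerance_frac x mask_width`` of the mask's half-area
    column; a drooping leaf tip may lie lower than the stem base but off the
    midline, and is then classified as a leaf tip.  If no endpoint passes the
    midline test, the lowest endpoint is used as a fallback and the record is
    flagged ``stem_start_fallback``.
    """
    if config is None:
        config = PipelineConfig()
    skel = np.asarray(skel, dtype=bool)
    if not skel.any():
        raise SkeletonError("empty skeleton")
    endpoints = skeleton_endpoints(skel)
    branch_points = branch_point_clusters(skel)
    rows, cols = np.nonzero(skel)
    com = (float(rows.mean()), float(cols.mean()))

    flags: list[str] = []
    stem_start: tuple[int, int] | None = None
    if endpoints:
        mid_col = half_area_column(mask)
        mcols = np.nonzero(np.asarray(mask, dtype=bool).any(axis=0))[0]
        mask_width = int(mcols[-1] - mcols[0] + 1)
        tol = config.midline_tolerance_frac * mask_width
        qualifying = [p for p in endpoints if abs(p[1] - mid_col) <= tol]
        if qualifying:
            stem_start = max(qualifying, key=lambda p: (p[0], -p[1]))
        else:
            flags.append("stem_start_fallback")
            stem_start = max(endpoints, key=lambda p: (p[0], -p[1]))
    else:
        flags.append("stem_start_not_found")

    leaf_tips = [p for p in endpoints if p != stem_start]
    return PointsOfInterest(
        leaf_tips=leaf_tips,
        branch_points=branch_points,
        stem_start=stem_start,
        center_of_mass=com,
        flags=flags,
    )
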