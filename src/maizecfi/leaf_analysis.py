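"""Leaf labelling and per-leaf traits: area and tip-to-stem angle.

Subtracting the segmented stem from the plant mask leaves the leaves as
separate blobs (plus the whorl — the cluster of unexpanded leaves at the top
of a young maize plant).  The whorl is identified as the blob with the highest
centre of mass and excluded from the expanded-leaf count.  Remaining leaves
are ranked bottom-up by centre of mass (rank 1 = lowest = oldest), matching
the phytomer order for non-drooping plants.

The leaf-tip-to-stem angle is measured at the leaf's attachment point (the
stem-path pixel nearest the blob) between the local *upward* stem direction
and the vector to the leaf tip: upright leaves give small angles, drooping
leaves angles above 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NoPlantError
from .imaging_io import Calibration, PipelineConfig

__all__ = [
    "LeafTraits",
    "LeafSet",
    "separate_leaves",
    "remove_whorl",
    "rank_leaves",
    "leaf_area",
    "leaf_angle",
    "analyze_leaves",
]


@dataclass
class LeafTraits:
    """One labelled leaf: rank (1 = lowest), blob mask, area, tip and angle.

    ``angle_deg`` and ``tip`` are ``None`` for occluded/merged blobs that
    contain zero or multiple skeleton leaf tips — those carry area only and
    the ``occluded_or_merged`` flag.
    """

    rank: int
    blob_mask: np.ndarray
    area_cm2: float
    center_of_mass: tuple[float, float]
    tip: tuple[int, int] | None = None
    attachment: tuple[int, int] | None = None
    angle_deg: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class LeafSet:
    """All leaf blobs of one plant, plus the whorl and pixel accounting.

    ``discarded_px`` counts sub-threshold fragment pixels dropped during blob
    separation, so that plant mask pixels are exactly conserved:
    ``|plant| = |stem| + |whorl| + sum(|leaf blobs|) + discarded_px``.
    """

    leaves: list[LeafTraits]
    whorl_mask: np.ndarray | None
    discarded_px: int
    n_discarded_fragments: int
    flags: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


def separate_leaves(
    plant_mask: np.ndarray,
    stem_mask: np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[list[np.ndarray], int, int]:
    """Connected components of ``plant_mask \\ stem_mask``.

    Components smaller than ``min_component_px`` are discarded as fragments;
    their pixel total and count are returned for exact pixel accounting.

    Returns ``(blobs, discarded_px, n_discarded)``.  Raises
    :class:`NoPlantError` if the difference is empty ("no leaves").
    """
    if config is None:
        config = PipelineConfig()
    plant_mask = np.asarray(plant_mask, dtype=bool)
    stem_mask = np.asarray(stem_mask, dtype=bool)
    residual = plant_mask & ~stem_mask
    if not residual.any():
        raise NoPlantError("no leaves: stem mask covers the whole plant")
    structure = ndimage.generate_binary_structure(2, 2 if config.connectivity == 8 else 1)
    labels, n = ndimage.label(residual, structure=structure)
    blobs: list[np.ndarray] = []
    discarded_px = 0
    n_discarded = 0
    sizes = np.bincount(labels.ravel())
    for i in range(1, n + 1):
        if sizes[i] >= config.min_component_px:
            blobs.append(labels == i)
        else:
            discarded_px += int(sizes[i])
            n_discarded += 1
    if not blobs:
        raise NoPlantError("no leaves: all residual components below size threshold")
    return blobs, discarded_px, n_discarded


def _blob_com(blob: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(blob)
    return float(rows.mean()), float(cols.mean())


def remove_whorl(blobs: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Split off the whorl: the blob whose centre of mass is highest in the image.

    With a single blob, that blob is the whorl and zero expanded leaves remain.
    Returns ``(whorl_blob, remaining_blobs)``.
    """
    if not blobs:
        raise NoPlantError("no blobs to classify")
    coms = [_blob_com(b) for b in blobs]
    # highest centre of mass = smallest row; deterministic tie-break by column
    k = min(range(len(blobs)), key=lambda i: (coms[i][0], coms[i][1]))
    whorl = blobs[k]
    remaining = [b for i, b in enumerate(blobs) if i != k]
    return whorl, remaining


def rank_leaves(blobs: list[np.ndarray], cal: Calibration) -> list[LeafTraits]:
    """Rank leaf blobs bottom-up by centre of mass and attach areas.

    The lowest blob is rank 1 (the oldest leaf); ties break toward the smaller
    centre-of-mass column.
    """
    coms = [_blob_com(b) for b in blobs]
    order = sorted(range(len(blobs)), key=lambda i: (-coms[i][0], coms[i][1]))
    return [
        LeafTraits(
            rank=rank,
            blob_mask=blobs[i],
            area_cm2=leaf_area(blobs[i], cal),
            center_of_mass=coms[i],
        )
        for rank, i in enumerate(order, start=1)
    ]


def leaf_area(blob: np.ndarray, cal: Calibration) -> float:
    """Side-projected leaf area: blob pixel count scaled to cm^2."""
    return cal.area_cm2(int(np.asarray(blob, dtype=bool).sum()))


def _local_stem_direction(
    path: list[tuple[int, int]], index: int, inner: int = 6, outer: int = 24
) -> np.ndarray:
    """Unit (row, col) vector along the stem path toward the top node.

    A principal-axis fit over the path pixels ``inner``..``outer`` steps away
    from the attachment on either side.  The pixels immediately at the
    junction are excluded because thinning bends the skeleton toward the
    departing blade there, which would tilt the direction estimate; a
    principal-axis (SVD) fit is used because near-vertical paths degenerate
    under a column-on-row regression.  The sign points toward increasing path
    index, i.e. toward the top node.
    """
    idxs = [
        j
        for j in range(len(path))
        if inner <= abs(j - index) <= outer
    ]
    if len(idxs) < 2:  # very short path: use everything
        idxs = list(range(len(path)))
    pts = np.asarray([path[j] for j in idxs], dtype=float)
    if len(pts) < 2:
        return np.array([-1.0, 0.0])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    chord = pts[-1] - pts[0]
    if np.dot(direction, chord) < 0:
        direction = -direction
    norm = np.linalg.norm(direction)
    return direction / norm if norm > 0 else np.array([-1.0, 0.0])


def leaf_angle(
    leaf: LeafTraits,
    path: list[tuple[int, int]],
    tips: list[tuple[int, int]],
) -> LeafTraits:
    """Measure the leaf-tip-to-stem angle for one blob, in place.

    The leaf's two extremity points are its skeleton tip and its attachment
    (the stem-path pixel nearest the blob).  The angle is between the
    attachment-to-tip vector and the stem's local upward direction at the
    attachment, in ``[0, 180]`` degrees.  Blobs containing zero or >= 2 tips
    (occluded or merged leaves) get no angle and are flagged.
    """
    blob = leaf.blob_mask
    in_blob = [t for t in tips if blob[t[0], t[1]]]
    if len(in_blob) != 1:
        leaf.flags.append("occluded_or_merged")
        return leaf
    tip = in_blob[0]

    # attachment = path pixel nearest the blob (distance transform to the blob)
    dist_to_blob = ndimage.distance_transform_edt(~blob)
    dvals = [dist_to_blob[r, c] for r, c in path]
    attach_idx = int(np.argmin(dvals))
    attachment = path[attach_idx]

    up = _local_stem_direction(path, attach_idx)
    v = np.array([tip[0] - attachment[0], tip[1] - attachment[1]], dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        leaf.flags.append("degenerate_tip")
        return leaf
    cosang = np.clip(np.dot(v, up) / nv, -1.0, 1.0)
    leaf.tip = tip
    leaf.attachment = attachment
    leaf.angle_deg = float(np.degrees(np.arccos(cosang)))
    return leaf


def analyze_leaves(
    plant_mask: np.ndarray,
    stem_mask: np.ndarray,
    path: list[tuple[int, int]],
    tips: list[tuple[int, int]],
    config: PipelineConfig | None = None,
) -> LeafSet:
    """Full leaf stage: separate, remove whorl, rank, measure areas and angles."""
    if config is None:
        config = PipelineConfig()
    blobs, discarded_px, n_discarded = separate_leaves(plant_mask, stem_mask, config)
    flags: list[str] = []
    whorl, remaining = remove_whorl(blobs)
    if not remaining:
        flags.append("no_expanded_leaves")
    leaves = rank_leaves(remaining, config.calibration)
    for leaf in leaves:
        leaf_angle(leaf, path, tips)
    return LeafSet(
        leaves=leaves,
        whorl_mask=whorl,
        discarded_px=discarded_px,
        n_discarded_fragments=n_discarded,
        flags=flags,
    )
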