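"""Procedural fluorescence-like maize renders with exact per-organ ground truth.

Every pipeline stage is testable without greenhouse data: a plant silhouette
(tapered stalk + arched leaves + an apical whorl cluster) is rendered bright
on a dark background, mimicking the chlorophyll-fluorescence imaging regime in
which plant tissue vastly outshines the background.  Each organ writes its own
label into a companion label image (0 = background, 1 = stem, 2.. = leaves in
phytomer order, 255 = whorl), and the ground truth is *measured from that
label image* (areas by pixel count, tips by farthest labelled pixel), so that
recovery tests quantify algorithm error rather than rendering error.

Geometry emulates vegetative-stage maize: leaves alternate sides of the
stalk, older (lower) leaves droop while younger (upper) leaves stand upright,
the stalk is widest near the base and tapers toward the top node, and the
whorl of unexpanded leaves sits above the youngest fully expanded leaf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import InputError
from .imaging_io import GrayImage

__all__ = [
    "LeafSpec",
    "SyntheticPlantSpec",
    "GroundTruth",
    "render_plant",
    "default_suite",
    "WHORL_LABEL",
    "STEM_LABEL",
]

STEM_LABEL = 1
WHORL_LABEL = 255
#: leaves taper linearly down to this blade width at the tip (px); wide enough
#: that morphological opening of the mask does not erode the tip.
_TIP_WIDTH_PX = 5.0
#: fraction of the stalk (from the base) rendered at constant full width; the
#: taper to the top-node width happens above this point.
_TAPER_ONSET = 0.6


@dataclass(frozen=True)
class LeafSpec:
    """Geometry of a single fully expanded leaf.

    ``attach_frac`` is the height of the attachment node as a fraction of stem
    height (0 = base, 1 = top node).  ``tip_angle_deg`` is the angle between
    the attachment-to-tip chord and the upward stem direction (small = upright,
    > 90 = drooping).  ``curvature`` bows the blade upward as a fraction of the
    chord length.
    """

    attach_frac: float
    length_px: float
    max_width_px: float
    tip_angle_deg: float
    side: str  # "left" or "right"
    curvature: float = 0.08


@dataclass(frozen=True)
class SyntheticPlantSpec:
    """Full parameterisation of one rendered plant."""

    image_h_px: int = 1120
    image_w_px: int = 1280
    cm_per_px: float = 0.05
    stem_base_row: int = 900
    stem_col: int = 640
    stem_height_px: int = 300
    stem_base_width_px: float = 22.0
    stem_top_width_px: float = 18.0
    leaves: tuple[LeafSpec, ...] = ()
    whorl_n_blades: int = 4
    whorl_blade_length_px: float = 150.0
    whorl_blade_width_px: float = 8.0
    whorl_lean_deg: float = 0.0
    #: partially expanded (uncollared) leaves arching out of the whorl, as
    #: (tip_angle_deg, length_px) pairs; they alternate sides starting
    #: opposite the youngest expanded leaf and belong to the whorl, not the
    #: expanded-leaf count.  Keeping them near-vertical and side-balanced
    #: keeps the skeleton's centre of mass on the stalk axis
    whorl_arcs: tuple[tuple[float, float], ...] = ((18.0, 260.0), (18.0, 220.0))
    fg_mean: float = 200.0
    fg_sd: float = 8.0
    bg_mean: float = 20.0
    bg_sd: float = 5.0
    blur_sigma: float = 0.0
    seed: int = 0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.fg_mean - self.bg_mean < 5.0 * max(self.fg_sd, self.bg_sd):
            raise InputError("insufficient foreground/background contrast (need >= 5 sd)")
        fracs = [lf.attach_frac for lf in self.leaves]
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise InputError("leaf attachments must be strictly ordered along the stem")
        if self.leaves and not np.isclose(fracs[-1], 1.0):
            raise InputError("the youngest expanded leaf must attach at the top node")

    @property
    def top_node(self) -> tuple[int, int]:
        """The attachment of the youngest expanded leaf (== stem top)."""
        return (self.stem_base_row - self.stem_height_px, self.stem_col)


@dataclass
class GroundTruth:
    """Exact organ-level truth measured on the rendered label image."""

    label_image: np.ndarray
    height_cm: float
    width_cm: float
    area_cm2: float
    stem_height_cm: float
    mid_stem_diameter_cm: float
    n_expanded_leaves: int
    leaf_labels: list[int]
    leaf_areas_cm2: list[float]
    leaf_tip_angles_deg: list[float]
    leaf_tips: list[tuple[int, int]]
    top_node: tuple[int, int]
    stem_base: tuple[int, int]

    @property
    def mask(self) -> np.ndarray:
        return self.label_image > 0


# ---------------------------------------------------------------------------
# rasterisation


def _stamp_disks(
    label: np.ndarray,
    pts: np.ndarray,
    radii: np.ndarray,
    value: int,
    overwrite: bool,
) -> None:
    """Stamp a disk at every curve sample into the label image.

    ``overwrite=False`` paints only background pixels, so earlier organs keep
    their labels where organs touch.  Raises if any disk reaches the canvas
    border (the spec is invalid: the plant must fit the frame).
    """
    h, w = label.shape
    rmax = float(np.max(radii))
    if (
        pts[:, 0].min() - rmax < 1
        or pts[:, 0].max() + rmax > h - 2
        or pts[:, 1].min() - rmax < 1
        or pts[:, 1].max() + rmax > w - 2
    ):
        raise InputError("organ leaves the canvas: spec invalid")
    for (r, c), rad in zip(pts, radii):
        r0, r1 = int(np.floor(r - rad)), int(np.ceil(r + rad)) + 1
        c0, c1 = int(np.floor(c - rad)), int(np.ceil(c + rad)) + 1
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        block = label[r0:r1, c0:c1]
        if overwrite:
            block[inside] = value
        else:
            block[inside & (block == 0)] = value


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, ts: np.ndarray) -> np.ndarray:
    ts = ts[:, None]
    return (1 - ts) ** 2 * p0 + 2 * ts * (1 - ts) * p1 + ts**2 * p2


def _leaf_points(
    spec: SyntheticPlantSpec, leaf: LeafSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sampled centreline points, per-sample radii, attachment and tip (float)."""
    attach = np.array(
        [spec.stem_base_row - leaf.attach_frac * spec.stem_height_px, spec.stem_col]
    )
    theta = np.radians(leaf.tip_angle_deg)
    s = 1.0 if leaf.side == "right" else -1.0
    chord = np.array([-leaf.length_px * np.cos(theta), s * leaf.length_px * np.sin(theta)])
    tip = attach + chord
    # bow the blade upward: normal of the chord pointing toward smaller rows
    normal = np.array([-abs(chord[1]), np.sign(chord[1]) * chord[0]])
    nn = np.linalg.norm(normal)
    normal = normal / nn if nn > 0 else np.array([-1.0, 0.0])
    if normal[0] > 0:
        normal = -normal
    ctrl = (attach + tip) / 2 + leaf.curvature * leaf.length_px * normal
    n_samples = max(8, int(np.ceil(2.5 * leaf.length_px)))
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = _bezier(attach, ctrl, tip, ts)
    widths = leaf.max_width_px + ((_TIP_WIDTH_PX - leaf.max_width_px) * ts)
    return pts, widths / 2.0, attach, tip


def _stem_width(spec: SyntheticPlantSpec, frac: float) -> float:
    """Stalk width at height fraction ``frac``.

    Constant over the lower stalk, tapering to the top-node width above
    ``_TAPER_ONSET``.  The bottom few pixels also taper to a point at the
    soil line: the medial axis of a pointed base ends exactly at the stem
    base pixel, whereas a blunt (flat or round) base splits the axis into
    cap branches whose endpoint wanders by up to half the stalk width.
    """
    # shallow enough that morphological closing cannot fill the notch between
    # the taper and the full-width stalk
    base_taper = min(30.0 / spec.stem_height_px, 0.12)
    if frac < base_taper:
        return _TIP_WIDTH_PX + (spec.stem_base_width_px - _TIP_WIDTH_PX) * frac / base_taper
    if frac <= _TAPER_ONSET:
        return spec.stem_base_width_px
    t = (frac - _TAPER_ONSET) / (1.0 - _TAPER_ONSET)
    return spec.stem_base_width_px + t * (spec.stem_top_width_px - spec.stem_base_width_px)


def render_plant(spec: SyntheticPlantSpec) -> tuple[GrayImage, GroundTruth]:
    """Render a plant and measure its ground truth from the label image.

    Deterministic for a fixed ``spec.seed`` (only pixel noise is random; the
    geometry is a pure function of the spec).
    """
    h, w = spec.image_h_px, spec.image_w_px
    label = np.zeros((h, w), dtype=np.uint16)

    # stalk: vertical thick line, full width below the taper onset
    n_samples = max(8, int(np.ceil(2.5 * spec.stem_height_px)))
    fracs = np.linspace(0.0, 1.0, n_samples)
    stem_pts = np.stack(
        [spec.stem_base_row - fracs * spec.stem_height_px, np.full(n_samples, spec.stem_col)],
        axis=1,
    )
    stem_radii = np.array([_stem_width(spec, f) / 2.0 for f in fracs])
    _stamp_disks(label, stem_pts, stem_radii, STEM_LABEL, overwrite=True)

    # junction fillets (leaf sheaths): a slightly larger stem-labelled disk at
    # every attachment smooths the acute leaf/stalk wedge so that morphological
    # closing of the segmented mask adds no pixels there; the fillet is offset
    # a little toward the leaf so it never protrudes on the far side of the
    # stalk (a protruding crescent would survive stem subtraction as a blob)
    leaf_geom = [_leaf_points(spec, lf) for lf in spec.leaves]
    for lf, (pts, radii, attach, tip) in zip(spec.leaves, leaf_geom):
        if np.isclose(lf.attach_frac, 1.0):
            # at the top node the fillet must stay within the stalk radius,
            # or it would bridge the youngest blade to the whorl outside the
            # future stem mask
            fillet_r = _stem_width(spec, 1.0) / 2.0 + 1.5
            center = attach
        else:
            fillet_r = max(_stem_width(spec, lf.attach_frac), lf.max_width_px) / 2.0 + 1.5
            u = (tip - attach) / np.linalg.norm(tip - attach)
            center = attach + 3.0 * u
        _stamp_disks(label, center[None, :], np.array([fillet_r]), STEM_LABEL, overwrite=True)

    # leaves, oldest first; they never overwrite the stalk or each other
    for idx, (pts, radii, _, _) in enumerate(leaf_geom):
        _stamp_disks(label, pts, radii, 2 + idx, overwrite=False)

    # apical whorl: a cluster of near-vertical unexpanded blades splaying from
    # the top node; they are furled tight at the base and widen upward, and
    # the whole cluster leans slightly away from the youngest expanded leaf
    # (so the two part ways right above the node, as in a real plant the leaf
    # collar sits just below the whorl)
    top = np.array(spec.top_node, dtype=float)
    if spec.whorl_n_blades > 0:
        fillet_r = spec.stem_top_width_px / 2.0 + 1.5
        _stamp_disks(label, top[None, :], np.array([fillet_r]), STEM_LABEL, overwrite=True)
        angles = spec.whorl_lean_deg + np.linspace(-10.0, 10.0, spec.whorl_n_blades)
        for k, ang in enumerate(angles):
            a = np.radians(ang)
            length = spec.whorl_blade_length_px * (0.85 + 0.3 * (k % 2))
            end = top + length * np.array([-np.cos(a), np.sin(a)])
            ts = np.linspace(0.0, 1.0, max(8, int(np.ceil(2.5 * length))))
            pts = top + ts[:, None] * (end - top)
            radii = 2.0 + ts * (spec.whorl_blade_width_px / 2.0 - 2.0)
            _stamp_disks(label, pts, radii, WHORL_LABEL, overwrite=False)
        # uncollared leaves: large blades not yet staged, arching out of the
        # whorl on alternating sides (first opposite the youngest expanded
        # leaf); much of the young plant's upper mass
        top_sign = 1.0
        if spec.leaves:
            top_sign = 1.0 if spec.leaves[-1].side == "right" else -1.0
        for j, (ang, length) in enumerate(spec.whorl_arcs):
            a = np.radians(ang)
            side = -top_sign if j % 2 == 0 else top_sign
            chord = length * np.array([-np.cos(a), side * np.sin(a)])
            end = top + chord
            normal = np.array([-abs(chord[1]), np.sign(chord[1]) * chord[0]])
            nn = np.linalg.norm(normal)
            normal = normal / nn if nn > 0 else np.array([-1.0, 0.0])
            if normal[0] > 0:
                normal = -normal
            ctrl = (top + end) / 2 + 0.05 * length * normal
            ts = np.linspace(0.0, 1.0, max(8, int(np.ceil(2.5 * length))))
            pts = _bezier(top, ctrl, end, ts)
            radii = 2.5 + ts * 3.0 - ts**2 * 3.5
            _stamp_disks(label, pts, radii, WHORL_LABEL, overwrite=False)

    # regularise the silhouette to the fixpoint of morphological
    # opening-then-closing (disk radius 2, the pipeline default): the plant
    # *is* a morphologically regular shape, so a perfect segmentation of the
    # noiseless render reproduces the label foreground pixel-for-pixel.
    # Filled crevice pixels inherit the label of the nearest organ.
    fp = morphology.disk(2)
    mask = label > 0
    for _ in range(5):
        new = morphology.closing(morphology.opening(mask, fp), fp)
        if np.array_equal(new, mask):
            break
        mask = new
    label[~mask] = 0
    added = mask & (label == 0)
    if added.any():
        _, (ir, ic) = ndimage.distance_transform_edt(label == 0, return_indices=True)
        label[added] = label[ir[added], ic[added]]
    _, ncomp = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 2))
    if ncomp != 1:
        raise InputError("spec produces a fragmented silhouette")

    # intensities: bright fluorescing tissue on a dark background
    rng = np.random.default_rng(spec.seed)
    img = rng.normal(spec.bg_mean, spec.bg_sd, size=(h, w))
    fg = label > 0
    img[fg] = rng.normal(spec.fg_mean, spec.fg_sd, size=int(fg.sum()))
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    maxval = 2**spec.bit_depth - 1
    img = np.clip(np.round(img), 0, maxval)
    dtype = np.uint16 if spec.bit_depth == 16 else np.uint8
    image = GrayImage(pixels=img.astype(dtype), bit_depth=spec.bit_depth)

    return image, _measure_ground_truth(spec, label, leaf_geom)


def _measure_ground_truth(
    spec: SyntheticPlantSpec,
    label: np.ndarray,
    leaf_geom: list,
) -> GroundTruth:
    cm, cm2 = spec.cm_per_px, spec.cm_per_px**2
    mask = label > 0
    rows, cols = np.nonzero(mask)
    height_cm = (int(rows.max() - rows.min()) + 1) * cm
    width_cm = (int(cols.max() - cols.min()) + 1) * cm

    # mid-stalk diameter: median per-row stem-label width over the middle third
    # of the stalk (the median suppresses fillet-inflated rows)
    base_r, top_r = spec.stem_base_row, spec.stem_base_row - spec.stem_height_px
    lo = top_r + int(spec.stem_height_px / 3)
    hi = top_r + int(2 * spec.stem_height_px / 3)
    row_widths = (label[lo:hi] == STEM_LABEL).sum(axis=1)
    mid_diam_cm = float(np.median(row_widths[row_widths > 0])) * cm

    leaf_labels = [2 + i for i in range(len(spec.leaves))]
    leaf_areas = [float((label == lab).sum()) * cm2 for lab in leaf_labels]
    tips: list[tuple[int, int]] = []
    angles: list[float] = []
    up = np.array([-1.0, 0.0])
    for lab, (_, _, attach, _) in zip(leaf_labels, leaf_geom):
        lr, lc = np.nonzero(label == lab)
        d2 = (lr - attach[0]) ** 2 + (lc - attach[1]) ** 2
        k = int(np.argmax(d2))
        tip = (int(lr[k]), int(lc[k]))
        tips.append(tip)
        v = np.array([tip[0] - attach[0], tip[1] - attach[1]])
        angles.append(float(np.degrees(np.arccos(np.clip(v @ up / np.linalg.norm(v), -1, 1)))))

    return GroundTruth(
        label_image=label,
        height_cm=height_cm,
        width_cm=width_cm,
        area_cm2=float(mask.sum()) * cm2,
        stem_height_cm=spec.stem_height_px * cm,
        mid_stem_diameter_cm=mid_diam_cm,
        n_expanded_leaves=len(spec.leaves),
        leaf_labels=leaf_labels,
        leaf_areas_cm2=leaf_areas,
        leaf_tip_angles_deg=angles,
        leaf_tips=tips,
        top_node=spec.top_node,
        stem_base=(spec.stem_base_row, spec.stem_col),
    )


# ---------------------------------------------------------------------------
# graded suite


#: leaves per plant for each complexity tier, smallest (V4-like) to largest
#: (V10-like); only the largest tier deliberately renders overlapping leaves.
_TIER_LEAVES = [2, 3, 4, 5, 6, 8]
_OVERLAP_TIER = 8


def leaves_overlap(
    label: np.ndarray,
    leaf_labels: list[int],
    top_node: tuple[int, int] | None = None,
    margin: int = 2,
    junction_radius: float = 55.0,
) -> bool:
    """True if any two leaf blades come within ``margin`` px of each other.

    The youngest leaf and the whorl share the top node as their origin, so a
    disk of ``junction_radius`` around the top node is excluded from the
    whorl-vs-leaf comparison: that neighbourhood lies inside the stem mask
    and is subtracted before blob labelling anyway.
    """
    struct = ndimage.generate_binary_structure(2, 2)
    dilated = [
        ndimage.binary_dilation(label == lab, struct, iterations=margin)
        for lab in leaf_labels
    ]
    whorl = label == WHORL_LABEL
    if top_node is not None:
        rr, cc = np.mgrid[0 : label.shape[0], 0 : label.shape[1]]
        near_node = (rr - top_node[0]) ** 2 + (cc - top_node[1]) ** 2 <= junction_radius**2
        whorl = whorl & ~near_node
    whorl_dil = ndimage.binary_dilation(whorl, struct, iterations=margin)
    for i in range(len(dilated)):
        for j in range(i + 1, len(dilated)):
            if np.any(dilated[i] & (label == leaf_labels[j])):
                return True
        leaf_i = label == leaf_labels[i]
        if top_node is not None:
            leaf_i = leaf_i & ~near_node
        if np.any(dilated[i] & whorl) or np.any(whorl_dil & leaf_i):
            return True
    return False


def _organs_resolvable(spec: SyntheticPlantSpec, truth: GroundTruth) -> bool:
    """Check that subtracting a nominal stem leaves one blob per organ.

    The nominal stem is the set of pixels within half the base width of the
    stalk axis (what an ideal stem segmentation would remove).  The residual
    must decompose into exactly ``n_leaves + 1`` blobs, the highest of which
    is the whorl and the rest map one-to-one onto the leaf labels — the
    structural guarantee the non-overlap tiers advertise.
    """
    label = truth.label_image
    axis = np.zeros(label.shape, dtype=bool)
    r0, c0 = truth.top_node
    axis[r0 : truth.stem_base[0] + 1, c0] = True
    axis_dist = ndimage.distance_transform_edt(~axis)
    # the check must hold over a band of stem radii, because the estimated
    # stem radius runs a pixel or two above the nominal half-width
    half = spec.stem_base_width_px / 2.0
    return all(
        _resolvable_at(spec, truth, label, axis_dist <= r) for r in (half, half + 2.0)
    )


def _resolvable_at(
    spec: SyntheticPlantSpec,
    truth: GroundTruth,
    label: np.ndarray,
    near_axis: np.ndarray,
) -> bool:
    residual = truth.mask & ~near_axis
    struct = ndimage.generate_binary_structure(2, 2)
    blobs, n = ndimage.label(residual, structure=struct)
    sizes = np.bincount(blobs.ravel())
    ids = [i for i in range(1, n + 1) if sizes[i] >= 64]
    if len(ids) != truth.n_expanded_leaves + 1:
        return False
    # classify each blob by its dominant organ label; require a bijection
    # between blobs and {leaf labels} + {whorl}, with the whorl blob highest
    owners = {}
    for i in ids:
        organ_px = label[blobs == i]
        organ_px = organ_px[organ_px > 0]
        if organ_px.size == 0:
            return False
        vals, counts = np.unique(organ_px, return_counts=True)
        owners[i] = int(vals[np.argmax(counts)])
    if sorted(owners.values()) != sorted(truth.leaf_labels + [WHORL_LABEL]):
        return False
    com_rows = {i: np.nonzero(blobs == i)[0].mean() for i in ids}
    highest = min(ids, key=lambda i: com_rows[i])
    return owners[highest] == WHORL_LABEL


def _tier_spec(n_leaves: int, rng: np.random.Generator, overlap: bool = False) -> SyntheticPlantSpec:
    """One plant of the given complexity with mild random jitter.

    Older (lower) leaves droop, younger (upper) leaves stand upright — the
    monotone angle progression both matches maize habit and keeps same-side
    blades from crossing in the non-overlap tiers.
    """
    k = n_leaves
    stem_h = int(300 + 45 * (k - 2) + rng.integers(-15, 16))
    base_w = 26.0 + k + rng.uniform(-1, 1)
    angles = np.linspace(118.0, 66.0, k) + rng.uniform(-5, 5, size=k)
    angles[-1] = max(angles[-1], 66.0)  # youngest blade must clear the whorl
    angles = np.clip(angles, 35.0, 125.0)
    # the top internode elongates the most, so the youngest collar sits a
    # long internode above the older ones
    if k > 1:
        fracs = np.append(np.linspace(0.35, 0.78, k - 1), 1.0)
        step = fracs[1] - fracs[0]
        fracs[:-1] = fracs[:-1] + rng.uniform(-0.15, 0.15, size=k - 1) * step
    else:
        fracs = np.array([1.0])
    lengths = (220.0 + 24.0 * np.arange(k) + rng.uniform(-15, 15, size=k)).clip(180, 480)
    widths = rng.uniform(12.0, 17.0, size=k)
    curvatures = rng.uniform(0.03, 0.06, size=k)
    curvatures[-1] = 0.02  # a bowed top blade would lean back into the whorl
    phase = int(rng.integers(0, 2))  # which side the lowest leaf takes
    sides = ["left" if i % 2 == phase else "right" for i in range(k)]
    if overlap:
        # force two same-side blades to cross: a low upright blade under a
        # high drooping one
        angles[0], angles[2] = 48.0, 118.0
        sides[0] = sides[2] = "right"
        lengths[0] = max(lengths[0], 320.0)
        lengths[2] = max(lengths[2], 320.0)
    leaves = tuple(
        LeafSpec(
            attach_frac=float(fracs[i]),
            length_px=float(lengths[i]),
            max_width_px=float(widths[i]),
            tip_angle_deg=float(angles[i]),
            side=sides[i],
            curvature=float(curvatures[i]),
        )
        for i in range(k)
    )
    return SyntheticPlantSpec(
        stem_height_px=stem_h,
        stem_base_width_px=base_w,
        stem_top_width_px=0.8 * base_w,
        leaves=leaves,
        whorl_n_blades=int(rng.integers(6, 9)),
        whorl_blade_length_px=min(150.0 + 20.0 * k, (900 - stem_h - 45) / 1.15),
        whorl_arcs=tuple(
            (ang, f * lengths[-1])
            for ang, f in [(18.0, 0.9), (18.0, 0.75)] + ([(26.0, 0.65)] if k >= 5 else [])
        ),
        whorl_lean_deg=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def default_suite(
    n_plants: int, seed: int = 0
) -> list[tuple[SyntheticPlantSpec, GrayImage, GroundTruth]]:
    """A graded benchmark suite spanning small to large vegetative plants.

    Plants cycle through complexity tiers of 2..8 expanded leaves; tiers up to
    6 leaves carry a non-overlapping-leaf guarantee (enforced by deterministic
    resampling of the jitter), while the 8-leaf tier deliberately renders
    crossing blades to exercise occlusion handling.  Deterministic per seed.
    """
    if n_plants < 1:
        raise InputError("n_plants must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_plants):
        k = _TIER_LEAVES[i % len(_TIER_LEAVES)]
        overlap_tier = k == _OVERLAP_TIER
        for _attempt in range(12):
            spec = _tier_spec(k, rng, overlap=overlap_tier)
            try:
                image, truth = render_plant(spec)
            except InputError:
                continue
            if overlap_tier or (
                not leaves_overlap(truth.label_image, truth.leaf_labels, top_node=truth.top_node)
                and _organs_resolvable(spec, truth)
            ):
                break
        else:
            raise RuntimeError("could not realise a non-overlapping plant in 12 attempts")
        out.append((spec, image, truth))
    return out


def analytic_leaf_area_px(spec: SyntheticPlantSpec, leaf_index: int) -> float:
    """Closed-form area target for one leaf, in pixels.

    The blade is a tube of varying width around a quadratic arc, so its area
    is the integral of the width along the arc, restricted to the part outside
    the stalk-plus-sheath-fillet disk at the attachment (the stalk owns those
    pixels), plus the half-disk cap at the tip.  Used as a rendering-fidelity
    check: the rasterised label pixel count must agree within 10%.
    """
    leaf = spec.leaves[leaf_index]
    pts, radii, attach, _ = _leaf_points(spec, leaf)
    widths = 2.0 * radii
    seg = np.hypot(*(np.diff(pts, axis=0).T))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    fillet_r = max(_stem_width(spec, leaf.attach_frac), leaf.max_width_px) / 2.0 + 1.5
    mid_w = 0.5 * (widths[:-1] + widths[1:])
    outside = arc[1:] > fillet_r
    area = float(np.sum(mid_w[outside] * seg[outside]))
    return area + np.pi * radii[-1] ** 2 / 2.0


def angle_probe_spec(tip_angle_deg: float, seed: int = 0) -> SyntheticPlantSpec:
    """A two-leaf plant whose lower leaf has a prescribed tip angle.

    Used to measure angle recovery at controlled angles: the probed leaf
    attaches mid-stem where any angle in [25, 130] degrees stays clear of the
    whorl and of the (fixed, upright) youngest leaf on the opposite side.
    """
    probe = LeafSpec(
        attach_frac=0.5,
        length_px=290.0,
        max_width_px=14.0,
        tip_angle_deg=float(tip_angle_deg),
        side="right",
        curvature=0.04,
    )
    top = LeafSpec(
        attach_frac=1.0,
        length_px=300.0,
        max_width_px=14.0,
        tip_angle_deg=70.0,
        side="left",
        curvature=0.02,
    )
    return SyntheticPlantSpec(
        stem_height_px=320,
        stem_base_width_px=28.0,
        stem_top_width_px=22.4,
        leaves=(probe, top),
        whorl_n_blades=7,
        whorl_blade_length_px=190.0,
        whorl_arcs=((18.0, 270.0), (18.0, 225.0)),
        seed=seed,
    )


def suite_truth_table(suite) -> "object":
    """Ground-truth manifest of a suite as a DataFrame (one row per plant)."""
    import pandas as pd

    rows = []
    for i, (spec, _, truth) in enumerate(suite):
        rows.append(
            {
                "plant_id": f"synth_{i:03d}",
                "n_expanded_leaves": truth.n_expanded_leaves,
                "height_cm": truth.height_cm,
                "width_cm": truth.width_cm,
                "projected_area_cm2": truth.area_cm2,
                "stem_height_cm": truth.stem_height_cm,
                "stem_diameter_cm": truth.mid_stem_diameter_cm,
                "seed": spec.seed,
            }
        )
    return pd.DataFrame(rows)
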