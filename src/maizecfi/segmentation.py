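"""Plant-mask segmentation from a chlorophyll fluorescence image.

Fluorescing tissue is much brighter than the background, so a global Otsu
threshold on the intensity histogram separates plant from background without
any per-image tuning.  The binary mask is then regularised by morphological
opening and closing, small speckle components are dropped, and — under the
one-plant-per-image assumption — only the largest connected component is kept.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import DegenerateImageError, NoPlantError
from .imaging_io import GrayImage, PipelineConfig

__all__ = ["otsu_threshold", "binarize", "clean_mask", "segment_plant"]


def otsu_threshold(image: GrayImage) -> int:
    """Otsu's threshold of the intensity histogram.

    Returns the integer threshold ``t`` maximising the between-class variance
    of the background class (intensity ``< t``) versus the foreground class
    (``>= t``).  Ties are broken toward the smallest maximising ``t``.

    Raises
    ------
    DegenerateImageError
        If the image has fewer than two distinct intensity values.
    """
    px = image.pixels.ravel()
    n_bins = 2**image.bit_depth
    hist = np.bincount(px, minlength=n_bins).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image: histogram has a single bin")

    # Between-class variance for every candidate split t: background = bins
    # [0, t), foreground = bins [t, n_bins).  Cumulative moments give all
    # candidates at once.
    total = hist.sum()
    levels = np.arange(n_bins, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]  # background weight for t = 1 .. n_bins-1
    w1 = total - w0
    m0 = np.cumsum(hist * levels)[:-1]
    m1 = hist @ levels - m0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.full(n_bins - 1, -np.inf)
    var_between[valid] = (
        w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    )
    # index i corresponds to threshold t = i + 1; argmax takes the smallest tie
    return int(np.argmax(var_between)) + 1


def binarize(image: GrayImage, threshold: int) -> np.ndarray:
    """Binary mask with foreground = pixels whose intensity is ``>= threshold``.

    Pixels strictly below the threshold are background.
    """
    return image.pixels >= threshold


def clean_mask(mask: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Regularise a raw binary mask into a single-component plant mask.

    Morphological opening (removes speckle) then closing (fills pinholes) with
    a disk of radius ``morph_radius_px``, removal of connected components
    smaller than ``min_component_px``, and finally keep-largest-component —
    one plant per image is assumed, so pot reflections and other bright
    artifacts must not survive.

    Raises
    ------
    NoPlantError
        If nothing remains after cleanup.
    """
    if config is None:
        config = PipelineConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoPlantError("no plant detected: empty mask")
    if config.morph_radius_px > 0:
        footprint = morphology.disk(config.morph_radius_px)
        mask = morphology.opening(mask, footprint)
        mask = morphology.closing(mask, footprint)
    if not mask.any():
        raise NoPlantError("no plant detected: mask empty after cleanup")
    structure = ndimage.generate_binary_structure(2, 2 if config.connectivity == 8 else 1)
    labels, n = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    sizes[sizes < config.min_component_px] = 0  # speckle components
    if not sizes.any():
        raise NoPlantError("no plant detected: mask empty after cleanup")
    return labels == int(np.argmax(sizes))


def segment_plant(image: GrayImage, config: PipelineConfig | None = None) -> np.ndarray:
    """Full segmentation: Otsu threshold, binarize, clean."""
    t = otsu_threshold(image)
    return clean_mask(binarize(image, t), config)
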