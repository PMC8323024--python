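"""Image and table I/O, calibration, and pipeline configuration.

Raster convention used throughout the package: arrays are indexed ``(row, col)``,
0-based, with row increasing *downward* (standard raster order).  The "height" of
a pixel above the image bottom is therefore ``image_height_px - 1 - row``.

Physical calibration is a single isotropic scale ``cm_per_px`` per camera:
lengths scale linearly with it and areas with its square.  This replaces the
vendor-specific calibration functions used on the original imaging hardware,
which are not portable; a possible lens nonlinearity is not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError

__all__ = [
    "GrayImage",
    "Calibration",
    "PipelineConfig",
    "read_gray_image",
    "write_gray_image",
    "load_config",
    "write_traits_csv",
    "read_traits_csv",
]

#: BT.601 luma weights used when an RGB image must be collapsed to one channel.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A single-channel fluorescence image.

    Parameters
    ----------
    pixels : ndarray of shape (height_px, width_px)
        Non-negative integer intensities.
    bit_depth : {8, 16}
        Nominal sensor depth; intensities lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InputError(f"expected a 2-D intensity grid, got ndim={px.ndim}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise InputError(f"image too small: {px.shape} (minimum 32x32)")
        if self.bit_depth not in (8, 16):
            raise InputError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() > 2**self.bit_depth - 1):
            raise InputError("intensities outside the nominal bit-depth range")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Calibration:
    """Isotropic pixel-to-physical-unit scale for one camera.

    ``cm_per_px`` converts lengths; areas use ``cm_per_px ** 2`` (derived, never
    stored separately).
    """

    cm_per_px: float = 0.05
    camera_id: str = "side"

    def __post_init__(self) -> None:
        if not self.cm_per_px > 0:
            raise ConfigError(f"cm_per_px must be positive, got {self.cm_per_px}")

    @property
    def cm2_per_px2(self) -> float:
        return self.cm_per_px**2

    def length_cm(self, px: float) -> float:
        return float(px) * self.cm_per_px

    def area_cm2(self, px: float) -> float:
        return float(px) * self.cm_per_px**2


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable knobs of the trait-extraction pipeline.

    Attributes
    ----------
    morph_radius_px : int
        Disk radius for morphological opening/closing of the binary mask.
    min_component_px : int
        Connected components smaller than this are treated as noise.
    spur_length_px : int
        Terminal skeleton branches shorter than this are pruned as artifacts.
    midline_tolerance_frac : float
        Half-width (as a fraction of mask width) of the vertical band around the
        mask's half-area column inside which the stem start point must lie.
    median_window : int
        Odd window of the 1-D median filter applied to the stem radius profile.
    connectivity : {4, 8}
        Pixel connectivity used for connected-component labelling.
    calibration : Calibration
    """

    morph_radius_px: int = 2
    min_component_px: int = 64
    spur_length_px: int = 10
    midline_tolerance_frac: float = 0.05
    median_window: int = 11
    connectivity: int = 8
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        if self.morph_radius_px < 0:
            raise ConfigError("morph_radius_px must be >= 0")
        if self.min_component_px < 0:
            raise ConfigError("min_component_px must be >= 0")
        if self.spur_length_px < 0:
            raise ConfigError("spur_length_px must be >= 0")
        if not 0.0 <= self.midline_tolerance_frac <= 1.0:
            raise ConfigError("midline_tolerance_frac must lie in [0, 1]")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ConfigError(
                f"median_window must be an odd positive integer, got {self.median_window}"
            )
        if self.connectivity not in (4, 8):
            raise ConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")

    @property
    def skimage_connectivity(self) -> int:
        """Connectivity in scikit-image convention (1 = 4-conn, 2 = 8-conn)."""
        return 1 if self.connectivity == 4 else 2


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF image as a single-channel :class:`GrayImage`.

    RGB input is collapsed to luminance (0.299 R + 0.587 G + 0.114 B) with a
    warning — the fluorescence camera is monochrome, so colour input is only a
    fallback.  Single-channel input is returned with intensities unmodified.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio plugins raise assorted exception types
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise InputError(f"zero-size image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        warnings.warn(
            f"{path.name}: RGB input converted to luminance; the fluorescence "
            "camera is monochrome",
            stacklevel=2,
        )
        arr = np.round(arr[:, :, :3].astype(float) @ _LUMA)
    if arr.ndim != 2:
        raise InputError(f"unsupported image dimensionality {arr.shape}: {path}")
    bit_depth = 16 if arr.max(initial=0) > 255 or arr.dtype == np.uint16 else 8
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    return GrayImage(pixels=arr.astype(dtype), bit_depth=bit_depth)


def write_gray_image(image: GrayImage, path: str | Path) -> Path:
    """Write a :class:`GrayImage` to PNG or TIFF, preserving bit depth."""
    path = Path(path)
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    iio.imwrite(path, image.pixels.astype(dtype))
    return path


# ---------------------------------------------------------------------------
# configuration

_CONFIG_KEYS = {
    "morph_radius_px": int,
    "min_component_px": int,
    "spur_length_px": int,
    "midline_tolerance_frac": float,
    "median_window": int,
    "connectivity": int,
}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML key-value document.

    Missing keys take the documented defaults; ``None`` returns the full
    default configuration.  Recognised keys: the :class:`PipelineConfig`
    fields plus ``cm_per_px`` and ``camera_id`` for the calibration.
    """
    if path is None:
        return PipelineConfig()
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config document {path}: {exc}") from exc
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config must be a key-value mapping, got {type(doc).__name__}")

    kwargs = {}
    for key, caster in _CONFIG_KEYS.items():
        if key in doc:
            try:
                kwargs[key] = caster(doc[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid value for {key!r}: {doc[key]!r}") from exc
    cal_kwargs = {}
    if "cm_per_px" in doc:
        try:
            cal_kwargs["cm_per_px"] = float(doc["cm_per_px"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid cm_per_px: {doc['cm_per_px']!r}") from exc
    if "camera_id" in doc:
        cal_kwargs["camera_id"] = str(doc["camera_id"])
    unknown = set(doc) - set(_CONFIG_KEYS) - {"cm_per_px", "camera_id"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(calibration=Calibration(**cal_kwargs), **kwargs)


# ---------------------------------------------------------------------------
# trait tables

#: Plant-level CSV column order.
PLANT_COLUMNS = [
    "plant_id",
    "image_path",
    "height_cm",
    "width_cm",
    "projected_area_cm2",
    "stem_height_cm",
    "vertical_stem_height_cm",
    "stem_path_length_cm",
    "stem_diameter_cm",
    "n_leaves",
    "flags",
]

#: Per-leaf (long format) CSV column order.
LEAF_COLUMNS = ["plant_id", "leaf_rank", "leaf_area_cm2", "leaf_angle_deg"]


def write_traits_csv(
    records: Sequence["object"],
    path: str | Path,
    leaf_path: str | Path | None = None,
) -> Path:
    """Write plant-level trait records to CSV, plus a per-leaf companion file.

    ``records`` are :class:`~maizecfi.plant_traits.PlantRecord` objects (any
    object with ``to_row()`` / ``leaf_rows()`` methods is accepted).  Floats are
    written with 6 significant digits.  The companion per-leaf file is in long
    format (one row per leaf); its path defaults to ``<stem>_leaves.csv``.
    """
    if not records:
        raise InputError("no records to write")
    path = Path(path)
    if leaf_path is None:
        leaf_path = path.with_name(path.stem + "_leaves.csv")
    plant_df = pd.DataFrame([r.to_row() for r in records], columns=PLANT_COLUMNS)
    leaf_rows = [row for r in records for row in r.leaf_rows()]
    leaf_df = pd.DataFrame(leaf_rows, columns=LEAF_COLUMNS)
    try:
        plant_df.to_csv(path, index=False, float_format="%.6g")
        leaf_df.to_csv(leaf_path, index=False, float_format="%.6g")
    except OSError as exc:
        raise InputError(f"cannot write traits table: {exc}") from exc
    return path


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    """Read a traits table written by :func:`write_traits_csv`."""
    return pd.read_csv(path)
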