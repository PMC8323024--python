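"""End-to-end trait extraction for single images and batch directories.

Stage order: segment -> clean -> skeletonize -> trim -> landmarks -> top node
-> stem path/radius/mask -> leaf separation/whorl/rank/area/angle -> whole
plant traits.  A failure at any stage degrades gracefully to a flagged partial
record; one bad image never aborts a batch.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import leaf_analysis, plant_traits, segmentation, skeleton_analysis, stem_extraction
from .errors import MaizeCFIError, NoPlantError
from .imaging_io import GrayImage, PipelineConfig, write_traits_csv
from .plant_traits import PlantRecord

logger = logging.getLogger(__name__)

__all__ = ["analyze_image", "run_pipeline", "BatchResult", "check_pixel_conservation"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class BatchResult:
    """Outcome of a batch run: record lists and failure bookkeeping."""

    records: list[PlantRecord] = field(default_factory=list)
    n_full: int = 0
    n_partial: int = 0
    n_failed: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)


def check_pixel_conservation(record: PlantRecord, plant_mask: np.ndarray) -> bool:
    """Exact pixel accounting: plant = stem + whorl + leaves + discarded."""
    if record.stem is None or record.leafset is None:
        return True
    ls = record.leafset
    whorl = int(ls.whorl_mask.sum()) if ls.whorl_mask is not None else 0
    total = (
        int(record.stem.stem_mask.sum())
        + whorl
        + sum(int(leaf.blob_mask.sum()) for leaf in ls.leaves)
        + ls.discarded_px
    )
    return total == int(np.asarray(plant_mask, dtype=bool).sum())


def analyze_image(
    image: GrayImage,
    config: PipelineConfig | None = None,
    plant_id: str = "plant",
    image_path: str = "",
) -> PlantRecord:
    """Extract all traits from one side-view fluorescence image.

    Stages that cannot run leave their traits absent and add a flag; the
    record always carries whatever could be measured.
    """
    if config is None:
        config = PipelineConfig()
    cal = config.calibration
    record = PlantRecord(plant_id=plant_id, image_path=image_path)
    t0 = time.perf_counter()

    try:
        mask = segmentation.segment_plant(image, config)
    except MaizeCFIError as exc:
        record.flags.append("no_plant_detected")
        logger.warning("%s: %s", plant_id, exc)
        return record

    record.height_cm, record.width_cm, record.projected_area_cm2 = (
        plant_traits.whole_plant_traits(mask, cal)
    )

    try:
        skel = skeleton_analysis.skeletonize_mask(mask)
        skel = skeleton_analysis.trim_spurs(skel, config.spur_length_px)
        poi = skeleton_analysis.find_landmarks(skel, mask, config)
        record.flags.extend(poi.flags)
    except MaizeCFIError as exc:
        record.flags.append("skeleton_failed")
        logger.warning("%s: skeleton stage failed: %s", plant_id, exc)
        return record

    try:
        record.stem = stem_extraction.extract_stem(skel, mask, poi, config)
        record.flags.extend(record.stem.flags)
    except MaizeCFIError as exc:
        record.flags.append("no_top_node")
        logger.info("%s: stem stage skipped: %s", plant_id, exc)
        return record

    try:
        record.leafset = leaf_analysis.analyze_leaves(
            mask, record.stem.stem_mask, record.stem.path, poi.leaf_tips, config
        )
        record.flags.extend(record.leafset.flags)
        for leaf in record.leafset.leaves:
            for f in leaf.flags:
                record.flags.append(f"leaf{leaf.rank}:{f}")
    except NoPlantError as exc:
        record.flags.append("no_leaves")
        logger.info("%s: leaf stage skipped: %s", plant_id, exc)

    if not check_pixel_conservation(record, mask):
        record.flags.append("pixel_conservation_violation")

    logger.info(
        "%s: done in %.2fs (flags: %s)", plant_id, time.perf_counter() - t0,
        ";".join(record.flags) or "-",
    )
    return record


def run_pipeline(
    image_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> BatchResult:
    """Run the full pipeline over every image in a directory.

    Writes plant-level and per-leaf CSVs into ``out_dir`` when given.  Records
    with stem and leaves count as full; records with flags but some traits as
    partial; unreadable images as failed.
    """
    from .imaging_io import read_gray_image

    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not paths:
        raise MaizeCFIError(f"no readable images in {image_dir}")

    result = BatchResult()
    for path in paths:
        try:
            image = read_gray_image(path)
        except MaizeCFIError as exc:
            result.n_failed += 1
            result.failures.append((path.name, str(exc)))
            logger.error("%s: unreadable (%s)", path.name, exc)
            continue
        record = analyze_image(image, config, plant_id=path.stem, image_path=str(path))
        result.records.append(record)
        if record.stem is not None and record.leafset is not None and not record.flags:
            result.n_full += 1
        else:
            result.n_partial += 1

    if out_dir is not None and result.records:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_traits_csv(result.records, out_dir / "plant_traits.csv")
    return result
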