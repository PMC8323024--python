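"""Debug overlays: segmentation mask, landmark markers, labelled leaves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .imaging_io import GrayImage
from .plant_traits import PlantRecord

__all__ = ["save_debug_figure", "save_mask_png"]


def save_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit 0/255 PNG."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
    return path


def save_debug_figure(image: GrayImage, record: PlantRecord, path: str | Path) -> Path:
    """One-panel overlay: image, stem path, landmarks, leaf ranks."""
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.imshow(image.pixels, cmap="gray")
    if record.stem is not None:
        pts = np.asarray(record.stem.path)
        ax.plot(pts[:, 1], pts[:, 0], "-", color="magenta", lw=1.5, label="stem path")
        ax.plot(pts[0, 1], pts[0, 0], "o", color="magenta", ms=9, label="stem start")
        ax.plot(pts[-1, 1], pts[-1, 0], "o", color="cyan", ms=7, label="top node")
    if record.leafset is not None:
        for leaf in record.leafset.leaves:
            r, c = leaf.center_of_mass
            ax.text(c, r, str(leaf.rank), color="yellow", fontsize=12, weight="bold")
            if leaf.tip is not None:
                ax.plot(leaf.tip[1], leaf.tip[0], "o", color="blue", ms=5)
    ax.set_title(f"{record.plant_id}  flags: {';'.join(record.flags) or '-'}")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
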