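"""Reading and writing tiles, masks and overlays (8-bit TIFF/PNG)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.segmentation import find_boundaries

from .segmentation import LabelMask
from .stain import RGBTile

__all__ = ["read_tile", "write_tile", "write_mask", "read_mask", "write_overlay"]


def read_tile(path: str | Path) -> RGBTile:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return RGBTile(pixels=arr[..., :3])


def write_tile(tile: RGBTile, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, tile.pixels)
    else:
        Image.fromarray(tile.pixels).save(path)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Label mask as 16-bit single-channel TIFF/PNG."""
    arr = mask.labels
    if arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    arr16 = arr.astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr16)
    else:
        Image.fromarray(arr16).save(path)


def read_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    return LabelMask(labels=arr.astype(np.int32))


def write_overlay(tile: RGBTile, mask: LabelMask, path: str | Path) -> None:
    """Nucleus boundaries drawn in green on the original RGB, for QC."""
    rgb = tile.pixels.copy()
    edges = find_boundaries(mask.labels, mode="outer")
    rgb[edges] = (0, 255, 0)
    Image.fromarray(rgb).save(path)
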