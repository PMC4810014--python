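"""Image reading and writing helpers (8-bit RGB TIFF/JPEG/PNG)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import FormatError

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as an (H, W, 3) uint8 RGB array; alpha is dropped."""
    try:
        arr = iio.imread(Path(path))
    except Exception as exc:  # unreadable / corrupt file
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def write_gradient_png(path: str | Path, magnitude: np.ndarray) -> None:
    """Dump a gradient-magnitude field as a 16-bit PNG (scaled to full range)."""
    mag = np.asarray(magnitude, dtype=float)
    top = mag.max()
    scaled = (mag / top * 65535.0) if top > 0 else mag
    iio.imwrite(Path(path), scaled.astype(np.uint16))
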