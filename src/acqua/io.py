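"""Raster I/O: TIFF and PNG in, float [0, 1] gray arrays out."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from acqua.errors import ValidationError
from acqua.preprocess import as_gray


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG micrograph as a [0, 1] float gray image."""
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"no such image: {p}")
    try:
        if p.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(p)
        else:
            arr = iio.imread(p)
    except Exception as exc:
        raise ValidationError(f"cannot read image {p}: {exc}") from exc
    return as_gray(arr)


def write_image(path, image: np.ndarray) -> None:
    """Write a float image as 32-bit TIFF, or 8-bit PNG for .png paths."""
    p = Path(path)
    arr = np.asarray(image)
    if p.suffix.lower() == ".png":
        lo, hi = float(arr.min()), float(arr.max())
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
        iio.imwrite(p, (scaled * 255).astype(np.uint8))
    else:
        tifffile.imwrite(p, arr.astype(np.float32))
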