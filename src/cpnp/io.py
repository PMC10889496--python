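"""Image reading and writing (PNG/TIFF) on the float 0-255 convention.

8-bit images map to [0, 255] directly; 16-bit integer images are rescaled
by 255/65535 on read and the inverse on 16-bit write.  Multi-channel images
are returned as ``(h, w, c)`` float arrays; the solvers operate channel-wise.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_image", "write_image"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF image as float64 on the 0-255 scale."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) * (255.0 / 65535.0)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64)
    return arr.astype(np.float64)


def write_image(path: str | Path, img: np.ndarray, bitdepth: int = 8) -> None:
    """Write a float 0-255 image as 8- or 16-bit PNG/TIFF, clipping at write time."""
    path = Path(path)
    img = np.asarray(img, dtype=np.float64)
    clipped = np.clip(img, 0.0, 255.0)
    if bitdepth == 8:
        out = np.round(clipped).astype(np.uint8)
    elif bitdepth == 16:
        out = np.round(clipped * (65535.0 / 255.0)).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
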