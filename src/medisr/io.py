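"""Single-channel image I/O (PNG/TIFF) and luminance conversion."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image to single-channel luminance; pass 2-D through."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        lum = image[..., :3].astype(np.float64) @ _LUMA
        if np.issubdtype(image.dtype, np.integer):
            return np.rint(lum).astype(image.dtype)
        return lum
    raise ValueError(f"cannot interpret image of shape {image.shape} as single channel")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a 2-D luminance array."""
    return to_luminance(iio.imread(path))


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a 2-D image as PNG/TIFF; float arrays are rounded to uint8."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("write_image expects a single-channel 2-D image")
    if not np.issubdtype(image.dtype, np.integer):
        image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), image)
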