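"""Image-quality evaluation: PSNR and region-wise comparison.

PSNR = 10 * log10(peak^2 / MSE) with peak = 2^n - 1 for bit depth n.
Region-wise PSNR supports the corners/edges-vs-plain comparison style:
tiles with high mean gradient magnitude are labelled "corners_edges",
the rest "plain".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class PsnrResult:
    psnr_db: float  # math.inf when the images are identical
    mse: float
    bit_depth: int

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.psnr_db)


@dataclass(frozen=True)
class RegionSpec:
    label: str  # "corners_edges" or "plain"
    box: Tuple[int, int, int, int]  # (row0, col0, row1, col1), 0-based half-open

    def __post_init__(self) -> None:
        if self.label not in ("corners_edges", "plain"):
            raise ValueError(f"unknown region label {self.label!r}")
        r0, c0, r1, c1 = self.box
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"empty or inverted region box {self.box}")


def _as_float_pair(reference, test):
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    return reference, test


def psnr(reference: np.ndarray, test: np.ndarray, bit_depth: int = 8) -> PsnrResult:
    """Peak signal-to-noise ratio in dB on the declared bit depth.

    Unit-interval float images should be scaled to the bit-depth peak by
    the caller (the pipeline does this) so PSNRs are comparable across
    integer and float paths.  Identical images yield the infinite
    sentinel (``math.inf``).
    """
    reference, test = _as_float_pair(reference, test)
    mse = float(np.mean((reference - test) ** 2))
    peak = 2**bit_depth - 1
    if mse == 0.0:
        return PsnrResult(psnr_db=math.inf, mse=0.0, bit_depth=bit_depth)
    return PsnrResult(psnr_db=10.0 * math.log10(peak**2 / mse), mse=mse, bit_depth=bit_depth)


def region_psnr(
    reference: np.ndarray,
    test: np.ndarray,
    regions: Sequence[RegionSpec],
    bit_depth: int = 8,
) -> List[Tuple[RegionSpec, PsnrResult]]:
    """PSNR restricted to each region's pixels."""
    reference, test = _as_float_pair(reference, test)
    out = []
    for region in regions:
        r0, c0, r1, c1 = region.box
        if not (0 <= r0 < r1 <= reference.shape[0] and 0 <= c0 < c1 <= reference.shape[1]):
            raise ValueError(f"region box {region.box} outside image {reference.shape}")
        out.append((region, psnr(reference[r0:r1, c0:c1], test[r0:r1, c0:c1], bit_depth)))
    return out


def classify_regions(image: np.ndarray, tile: int, threshold: float) -> List[RegionSpec]:
    """Tile the image and label each tile by mean gradient magnitude.

    Tiles whose mean |grad| exceeds ``threshold`` become corners_edges;
    the rest plain.  ``tile`` must divide both image dimensions.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if h % tile or w % tile:
        raise ValueError(f"tile {tile} does not divide image shape {image.shape}")
    gi, gj = np.gradient(image)
    mag = np.hypot(gi, gj)
    regions = []
    for r0 in range(0, h, tile):
        for c0 in range(0, w, tile):
            mean_grad = float(mag[r0 : r0 + tile, c0 : c0 + tile].mean())
            label = "corners_edges" if mean_grad > threshold else "plain"
            regions.append(RegionSpec(label=label, box=(r0, c0, r0 + tile, c0 + tile)))
    return regions
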