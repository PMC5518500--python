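"""Paired training-set construction: random HR crops and x4 LR counterparts.

Ground-truth patches (128x128 by default) are cut randomly and
repeatedly from a corpus; each is scaled down by an integer factor to
produce its low-resolution input (32x32 by default).  Scaling-down is
area averaging over factor x factor blocks — exact and deterministic —
with bicubic decimation available behind a flag.  Every pair carries
provenance (source id, crop origin, seed) sufficient to regenerate it
bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class TrainingPair:
    """(LR input, HR ground truth) with provenance for reproducibility."""

    lr: np.ndarray
    hr: np.ndarray
    source_id: str = ""
    crop_origin: Tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr.shape[0] != self.lr.shape[0] * 4 and self.hr.shape[0] % self.lr.shape[0] != 0:
            raise ValueError("HR side must be an integer multiple of the LR side")


@dataclass(frozen=True)
class CropRecord:
    source_index: int
    source_id: str
    origin: Tuple[int, int]


def crop_patches(
    images: Sequence[np.ndarray],
    size: int = 128,
    count: int = 1,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> Tuple[List[np.ndarray], List[CropRecord]]:
    """Cut ``count`` random size x size patches from a corpus.

    Sources are visited round-robin; within an image the crop origin is
    drawn uniformly with integer arithmetic from a seeded generator, so
    the crop list is identical across platforms for a given seed.
    Images smaller than ``size`` are skipped with a warning.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    usable = []
    for idx, img in enumerate(images):
        img = np.asarray(img)
        if img.ndim != 2:
            raise ValueError("corpus images must be single-channel 2-D arrays")
        if img.shape[0] < size or img.shape[1] < size:
            warnings.warn(f"corpus image {idx} is smaller than {size}x{size}; skipped")
            continue
        name = ids[idx] if ids is not None else f"img{idx:04d}"
        usable.append((idx, name, img))
    if not usable:
        raise ValueError("no corpus image is large enough for the requested crop size")
    rng = np.random.default_rng(seed)
    patches: List[np.ndarray] = []
    records: List[CropRecord] = []
    for k in range(count):
        idx, name, img = usable[k % len(usable)]
        r = int(rng.integers(0, img.shape[0] - size + 1))
        c = int(rng.integers(0, img.shape[1] - size + 1))
        patches.append(img[r : r + size, c : c + size].copy())
        records.append(CropRecord(source_index=idx, source_id=name, origin=(r, c)))
    return patches, records


def scale_down(image: np.ndarray, factor: int = 4, method: str = "area") -> np.ndarray:
    """Reduce an image by an integer factor.

    "area" (default) replaces each factor x factor block by its mean;
    for integer inputs the mean of a 16-pixel block is exact in float64.
    "bicubic" decimates through the cubic kernel (anti-alias-free point
    sampling of the bicubically smoothed image is deliberately not
    offered; this path uses local block prefiltering then sampling).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("scale_down expects a 2-D image")
    h, w = image.shape
    if h % factor or w % factor:
        raise ValueError(f"image shape {image.shape} not divisible by factor {factor}")
    if method == "area":
        blocks = image.reshape(h // factor, factor, w // factor, factor).astype(np.float64)
        return blocks.mean(axis=(1, 3))
    if method == "bicubic":
        from scipy.ndimage import zoom

        return zoom(image.astype(np.float64), 1 / factor, order=3, mode="nearest", grid_mode=True)
    raise ValueError(f"unknown scale_down method {method!r}")


def make_pairs(
    hr_patches: Sequence[np.ndarray],
    records: Sequence[CropRecord] | None = None,
    factor: int = 4,
    seed: int = 0,
) -> List[TrainingPair]:
    """One TrainingPair per HR patch, LR produced by area scale-down."""
    pairs = []
    for i, hr in enumerate(hr_patches):
        hr = np.asarray(hr)
        lr = scale_down(hr, factor=factor)
        rec = records[i] if records is not None else None
        pairs.append(
            TrainingPair(
                lr=lr,
                hr=hr.astype(np.float64),
                source_id=rec.source_id if rec else f"patch{i:04d}",
                crop_origin=rec.origin if rec else (0, 0),
                seed=seed,
            )
        )
    return pairs


def build_training_set(
    images: Sequence[np.ndarray],
    count: int,
    size: int = 128,
    factor: int = 4,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> List[TrainingPair]:
    """crop_patches + make_pairs in one call."""
    patches, records = crop_patches(images, size=size, count=count, seed=seed, ids=ids)
    return make_pairs(patches, records, factor=factor, seed=seed)
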