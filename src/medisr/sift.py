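"""SIFT features and the transfer-learning selection rule.

A small training corpus of target-domain (medical) images is enlarged
by admitting subregions of a generic image pool whose local structure
resembles the references.  Similarity is judged on SIFT features:

* ``sift_distance(S, T)`` — the mean, over the candidate's m
  descriptors, of the minimum Euclidean distance to the reference's
  descriptors (128-d each);
* ``match_ratio(S, T)`` — eta = N_m / N_t, the fraction of the
  candidate's features that find a match in the reference under
  nearest-neighbour matching with Lowe's ratio test;
* a candidate is admitted when ``eta >= D(S, T)``.

Descriptors are normalised to unit length, which puts D on the same
O(1) scale as the dimensionless ratio eta; independent eta/D threshold
overrides are exposed for callers who want to decouple the two sides of
the criterion.

The detector is a compact difference-of-Gaussians pipeline: per-octave
Gaussian stacks with geometric sigma spacing, strict 26-neighbour
extrema (8 in-plane + 9 above + 9 below), an absolute-contrast
threshold, dominant orientation from a 36-bin gradient histogram, and a
4x4-cell x 8-orientation-bin descriptor (128 values) sampled in the
rotated frame.  Subpixel refinement and Hessian edge rejection are
deliberately omitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter, minimum_filter
from scipy.spatial.distance import cdist

DESCRIPTOR_SIZE = 128  # 4 x 4 cells x 8 orientation bins


class EmptyFeatureSetError(ValueError):
    """Raised when a distance or ratio is requested on an empty feature set."""


@dataclass
class SiftFeature:
    x: float  # column coordinate in the original image
    y: float  # row coordinate
    scale: float  # sigma of the detection layer, original-image units
    orientation: float = 0.0  # degrees in [0, 360)
    descriptor: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.descriptor is not None:
            d = np.asarray(self.descriptor, dtype=np.float64)
            if d.shape != (DESCRIPTOR_SIZE,):
                raise ValueError(f"descriptor must have length {DESCRIPTOR_SIZE}, got {d.shape}")
            if (d < 0).any():
                raise ValueError("descriptor entries must be nonnegative")
            self.descriptor = d


@dataclass
class FeatureSet:
    image_id: str
    features: List[SiftFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def descriptor_matrix(self) -> np.ndarray:
        if not self.features:
            return np.zeros((0, DESCRIPTOR_SIZE))
        return np.stack([f.descriptor for f in self.features])


@dataclass
class ScaleSpacePyramid:
    octaves: List[dict]  # each: {"gaussians": [...], "dogs": [...], "sigmas": [...]}
    sigma0: float
    scales_per_octave: int


def _to_unit(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.size and image.max() > 1.5:  # integer-range input
        image = image / 255.0
    return image


def gaussian_scale_space(
    image: np.ndarray,
    octaves: int = 3,
    scales_per_octave: int = 3,
    sigma0: float = 1.6,
    assumed_blur: float = 0.5,
) -> ScaleSpacePyramid:
    """Per-octave Gaussian stacks with geometric sigma spacing, plus DoGs.

    Each octave holds ``scales_per_octave + 3`` smoothed images with
    within-octave sigmas ``sigma0 * 2^(i / s)`` and the adjacent
    differences (``s + 2`` DoG layers).  Octave o+1 starts from the
    layer at twice sigma0, downsampled by 2.  If the image is too small
    for the requested octave count it is reduced with a warning.
    """
    image = _to_unit(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("scale space needs a nonempty 2-D image")
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    max_octaves = 1
    m = min(image.shape)
    while m // 2 >= 8 and max_octaves < octaves:
        m //= 2
        max_octaves += 1
    if max_octaves < octaves:
        warnings.warn(f"image {image.shape} supports only {max_octaves} octaves; reducing")
        octaves = max_octaves
    s = scales_per_octave
    k = 2.0 ** (1.0 / s)
    base_blur = np.sqrt(max(sigma0**2 - assumed_blur**2, 0.01))
    current = gaussian_filter(image, base_blur, mode="reflect")
    pyramid: List[dict] = []
    for o in range(octaves):
        gaussians = [current]
        sigmas = [sigma0]
        for i in range(1, s + 3):
            prev_sigma = sigma0 * k ** (i - 1)
            inc = prev_sigma * np.sqrt(k * k - 1.0)
            gaussians.append(gaussian_filter(gaussians[-1], inc, mode="reflect"))
            sigmas.append(sigma0 * k**i)
        dogs = [gaussians[i + 1] - gaussians[i] for i in range(len(gaussians) - 1)]
        pyramid.append({"gaussians": gaussians, "dogs": dogs, "sigmas": sigmas})
        current = gaussians[s][::2, ::2]
    return ScaleSpacePyramid(octaves=pyramid, sigma0=sigma0, scales_per_octave=s)


def detect_keypoints(
    pyramid: ScaleSpacePyramid, contrast_threshold: float = 0.01
) -> List[SiftFeature]:
    """Strict extrema of the DoG stacks among their 26 neighbours.

    A pixel qualifies when its DoG value is strictly greater (or
    strictly smaller) than all 8 in-plane neighbours and the 9 + 9
    pixels in the scales above and below, and |DoG| exceeds the
    contrast threshold (unit intensity scale).  The threshold applies
    to raw adjacent-scale differences, which attenuate peak responses
    by roughly (k - 1) relative to a normalised Laplacian; 0.01 here
    corresponds to the conventional 0.03 on normalised responses.
    Positions and sigmas are mapped back to original-image
    coordinates.
    """
    features: List[SiftFeature] = []
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    for o, octave in enumerate(pyramid.octaves):
        dogs = np.stack(octave["dogs"])  # (L, H, W)
        if dogs.shape[0] < 3:
            continue
        neigh_max = maximum_filter(dogs, footprint=footprint, mode="constant", cval=-np.inf)
        neigh_min = minimum_filter(dogs, footprint=footprint, mode="constant", cval=np.inf)
        strict = (dogs > neigh_max) | (dogs < neigh_min)
        strict &= np.abs(dogs) > contrast_threshold
        strict[0] = strict[-1] = False  # need a full scale above and below
        strict[:, :1, :] = strict[:, -1:, :] = False  # 1-px spatial border
        strict[:, :, :1] = strict[:, :, -1:] = False
        step = 2**o
        for layer, r, c in zip(*np.nonzero(strict)):
            sigma = octave["sigmas"][layer] * step
            features.append(SiftFeature(x=float(c * step), y=float(r * step), scale=float(sigma)))
    return features


def _orientation(gi: np.ndarray, gj: np.ndarray, y: float, x: float, sigma: float) -> float:
    """Dominant gradient direction (degrees) from a 36-bin histogram."""
    h, w = gi.shape
    radius = max(int(round(3 * 1.5 * sigma)), 3)
    r0, r1 = max(int(y) - radius, 0), min(int(y) + radius + 1, h)
    c0, c1 = max(int(x) - radius, 0), min(int(x) + radius + 1, w)
    sub_i = gi[r0:r1, c0:c1]
    sub_j = gj[r0:r1, c0:c1]
    yy, xx = np.meshgrid(np.arange(r0, r1) - y, np.arange(c0, c1) - x, indexing="ij")
    weight = np.exp(-(yy**2 + xx**2) / (2 * (1.5 * sigma) ** 2))
    mag = np.hypot(sub_i, sub_j) * weight
    ang = np.degrees(np.arctan2(sub_i, sub_j)) % 360.0
    hist, _ = np.histogram(ang, bins=36, range=(0, 360), weights=mag)
    for _ in range(2):  # light circular smoothing stabilises the peak
        hist = (np.roll(hist, 1) + hist + np.roll(hist, -1)) / 3.0
    peak = int(np.argmax(hist))
    return (peak + 0.5) * 10.0


def _bilinear(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy = ys - y0
    fx = xs - x0
    y1 = np.clip(y0 + 1, 0, img.shape[0] - 1)
    x1 = np.clip(x0 + 1, 0, img.shape[1] - 1)
    y0 = np.clip(y0, 0, img.shape[0] - 1)
    x0 = np.clip(x0, 0, img.shape[1] - 1)
    return (
        img[y0, x0] * (1 - fy) * (1 - fx)
        + img[y0, x1] * (1 - fy) * fx
        + img[y1, x0] * fy * (1 - fx)
        + img[y1, x1] * fy * fx
    )


def describe_keypoints(
    image: np.ndarray,
    keypoints: Sequence[SiftFeature],
    clip: float = 0.2,
) -> Tuple[List[SiftFeature], int]:
    """Assign orientations and 128-d descriptors to detected keypoints.

    The descriptor samples a 16x16 grid (spacing = half the keypoint sigma)
    in the frame rotated to the dominant orientation, accumulates
    Gaussian-weighted gradient magnitudes into 4x4 cells x 8 orientation
    bins, normalises to unit length, clips at ``clip`` and renormalises.
    Keypoints whose sampling window leaves the image are dropped;
    returns (described features, dropped count).
    """
    image = _to_unit(image)
    grads: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}
    out: List[SiftFeature] = []
    dropped = 0
    offsets = np.arange(16) - 7.5
    oy, ox = np.meshgrid(offsets, offsets, indexing="ij")
    cell_r = (np.arange(16) // 4)[:, None] * np.ones(16, dtype=int)[None, :]
    cell_c = cell_r.T
    weight = np.exp(-(oy**2 + ox**2) / (2 * 8.0**2))
    for kp in keypoints:
        key = round(kp.scale, 3)
        if key not in grads:
            sm = gaussian_filter(image, kp.scale, mode="reflect")
            grads[key] = tuple(np.gradient(sm))
        gi, gj = grads[key]
        spacing = 0.5 * kp.scale
        # max sample offset is 7.5 * spacing * sqrt(2) after rotation
        margin = 10.7 * spacing
        if not (margin <= kp.y <= image.shape[0] - 1 - margin and margin <= kp.x <= image.shape[1] - 1 - margin):
            dropped += 1
            continue
        theta = _orientation(gi, gj, kp.y, kp.x, kp.scale)
        th = np.radians(theta)
        cos_t, sin_t = np.cos(th), np.sin(th)
        # rotate sample offsets into the image frame (x right, y down;
        # orientation measured from +x toward +y)
        sx = spacing * (ox * cos_t - oy * sin_t)
        sy = spacing * (ox * sin_t + oy * cos_t)
        ys = kp.y + sy
        xs = kp.x + sx
        sgi = _bilinear(gi, ys, xs)
        sgj = _bilinear(gj, ys, xs)
        mag = np.hypot(sgi, sgj) * weight
        ang = (np.degrees(np.arctan2(sgi, sgj)) - theta) % 360.0
        bins = (ang // 45.0).astype(int) % 8
        desc = np.zeros((4, 4, 8))
        np.add.at(desc, (cell_r, cell_c, bins), mag)
        vec = desc.ravel()
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec = np.minimum(vec / norm, clip)
            n2 = np.linalg.norm(vec)
            if n2 > 0:
                vec = vec / n2
        out.append(
            SiftFeature(x=kp.x, y=kp.y, scale=kp.scale, orientation=theta, descriptor=vec)
        )
    return out, dropped


def extract_features(
    image: np.ndarray,
    image_id: str = "",
    octaves: int = 3,
    scales_per_octave: int = 3,
    sigma0: float = 1.6,
    contrast_threshold: float = 0.01,
) -> FeatureSet:
    """Full pipeline: scale space -> keypoints -> described FeatureSet."""
    pyr = gaussian_scale_space(image, octaves=octaves, scales_per_octave=scales_per_octave, sigma0=sigma0)
    kps = detect_keypoints(pyr, contrast_threshold=contrast_threshold)
    feats, _ = describe_keypoints(image, kps)
    return FeatureSet(image_id=image_id, features=feats)


def sift_distance(s: FeatureSet, t: FeatureSet) -> float:
    """Mean-min descriptor distance D(S, T).

    The average over S's m descriptors of the minimum Euclidean
    distance to any of T's n descriptors.  Not symmetric in general.
    """
    if len(s) == 0 or len(t) == 0:
        raise EmptyFeatureSetError(
            f"D(S, T) undefined for empty sets (|S|={len(s)}, |T|={len(t)})"
        )
    d = cdist(s.descriptor_matrix(), t.descriptor_matrix())
    return float(d.min(axis=1).mean())


def match_features(s: FeatureSet, t: FeatureSet, ratio: float = 0.8) -> List[Tuple[int, int]]:
    """Nearest-neighbour matches with Lowe's ratio test.

    Feature i of S matches its nearest neighbour j in T when the
    nearest/second-nearest distance ratio is below ``ratio`` (a single
    reference feature always passes the test).
    """
    if len(s) == 0 or len(t) == 0:
        return []
    d = cdist(s.descriptor_matrix(), t.descriptor_matrix())
    matches = []
    for i in range(d.shape[0]):
        order = np.argsort(d[i])
        j = int(order[0])
        if d.shape[1] == 1 or d[i, j] < ratio * d[i, int(order[1])]:
            matches.append((i, j))
    return matches


def match_ratio(s: FeatureSet, t: FeatureSet, ratio: float = 0.8) -> float:
    """eta = N_m / N_t: matched pairs over the candidate's feature count."""
    if len(s) == 0:
        raise EmptyFeatureSetError("match ratio undefined: candidate has no features")
    if len(t) == 0:
        raise EmptyFeatureSetError("match ratio undefined: reference has no features")
    return len(match_features(s, t, ratio=ratio)) / len(s)


@dataclass(frozen=True)
class SelectionConfig:
    match_ratio_test: float = 0.8
    eta_threshold: Optional[float] = None  # override: admit iff eta >= this
    d_threshold: Optional[float] = None  # additional cap on D


@dataclass(frozen=True)
class SelectionDecision:
    candidate_id: str
    D: float
    eta: float
    admitted: bool
    best_reference: str = ""
    reason: str = ""


def select_candidates(
    candidates: Sequence[FeatureSet],
    references: Sequence[FeatureSet],
    config: SelectionConfig | None = None,
) -> List[SelectionDecision]:
    """Score each candidate against the references and apply eta >= D.

    D is aggregated as the minimum over references; eta is evaluated
    against that best-matching reference.  Candidates with no features
    are rejected outright and flagged.
    """
    config = config or SelectionConfig()
    refs = [r for r in references if len(r) > 0]
    if not refs:
        raise ValueError("selection requires at least one reference with features")
    decisions = []
    for cand in candidates:
        if len(cand) == 0:
            decisions.append(
                SelectionDecision(
                    candidate_id=cand.image_id, D=float("inf"), eta=0.0, admitted=False,
                    reason="no keypoints",
                )
            )
            continue
        dists = [(sift_distance(cand, r), r) for r in refs]
        d_best, r_best = min(dists, key=lambda p: p[0])
        eta = match_ratio(cand, r_best, ratio=config.match_ratio_test)
        if config.eta_threshold is not None:
            admitted = eta >= config.eta_threshold
            reason = f"eta >= {config.eta_threshold}" if admitted else "eta below threshold"
        else:
            admitted = eta >= d_best
            reason = "eta >= D" if admitted else "eta < D"
        if admitted and config.d_threshold is not None and d_best > config.d_threshold:
            admitted = False
            reason = "D above cap"
        decisions.append(
            SelectionDecision(
                candidate_id=cand.image_id, D=d_best, eta=eta, admitted=admitted,
                best_reference=r_best.image_id, reason=reason,
            )
        )
    return decisions


def tile_candidates(
    image: np.ndarray, image_id: str, size: int = 128, stride: int = 64
) -> List[Tuple[str, Tuple[int, int, int, int], np.ndarray]]:
    """Tile an image into candidate subregions (id, half-open box, crop)."""
    image = np.asarray(image)
    h, w = image.shape
    tiles = []
    for r0 in range(0, max(h - size, 0) + 1, stride):
        for c0 in range(0, max(w - size, 0) + 1, stride):
            box = (r0, c0, r0 + size, c0 + size)
            tiles.append((f"{image_id}[{r0}:{r0+size},{c0}:{c0+size}]", box, image[r0 : r0 + size, c0 : c0 + size]))
    return tiles
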