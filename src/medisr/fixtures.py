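"""Seeded synthetic image generators.

Every test and training input in this package is generated, never
downloaded: textured kinds (smooth noise, Gaussian blobs, checkerboard,
sinusoid) stand in for structured medical content, flat kinds (constant,
ramp) for feature-poor candidates.  Generation is deterministic given
the spec — NumPy's PCG64 generator seeded explicitly — so identical
specs produce identical arrays on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

KINDS = (
    "constant",
    "ramp",
    "sinusoid",
    "gaussian_blobs",
    "checkerboard",
    "smooth_noise",
    "step_edge",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    height: int = 64
    width: int = 64
    seed: int = 0
    params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.height < 1 or self.width < 1:
            raise ValueError("fixture dimensions must be positive")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "height": self.height,
            "width": self.width,
            "seed": self.seed,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        return cls(
            kind=d["kind"],
            height=int(d["height"]),
            width=int(d["width"]),
            seed=int(d.get("seed", 0)),
            params=dict(d.get("params", {})),
        )


def _grid(h: int, w: int):
    return np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")


def generate(spec: FixtureSpec, bit_depth: int = 8) -> np.ndarray:
    """Render a fixture spec to an integer image in [0, 2**bit_depth - 1].

    smooth_noise is white noise convolved with a Gaussian (default
    sigma 2), giving band-limited structure that a x4 super-resolver can
    actually learn from; gaussian_blobs places well-separated blobs so
    the blob count equals the count of smoothed local maxima.
    """
    peak = 2**bit_depth - 1
    h, w, p = spec.height, spec.width, spec.params
    rng = np.random.default_rng(spec.seed)
    ii, jj = _grid(h, w)
    if spec.kind == "constant":
        img = np.full((h, w), float(p.get("value", peak / 2)))
    elif spec.kind == "ramp":
        alpha = float(p.get("alpha", 1.0))
        beta = float(p.get("beta", 0.5))
        gamma = float(p.get("gamma", 10.0))
        img = alpha * ii + beta * jj + gamma
    elif spec.kind == "sinusoid":
        fi = float(p.get("freq_i", 0.05))
        fj = float(p.get("freq_j", 0.08))
        amp = float(p.get("amplitude", 0.4 * peak))
        img = peak / 2 + amp * np.sin(2 * np.pi * (fi * ii + fj * jj))
    elif spec.kind == "gaussian_blobs":
        k = int(p.get("n_blobs", 4))
        sigma = float(p.get("sigma", min(h, w) / 16))
        amp = float(p.get("amplitude", 0.6 * peak))
        background = float(p.get("background", 0.15 * peak))
        img = np.full((h, w), background)
        centers = _separated_centers(rng, h, w, k, min_dist=4.5 * sigma)
        for ci, cj in centers:
            img += amp * np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * sigma**2))
    elif spec.kind == "checkerboard":
        cell = int(p.get("cell", 8))
        lo = float(p.get("low", 0.1 * peak))
        hi = float(p.get("high", 0.9 * peak))
        board = ((ii // cell).astype(int) + (jj // cell).astype(int)) % 2
        img = np.where(board == 0, lo, hi)
    elif spec.kind == "smooth_noise":
        sigma = float(p.get("sigma", 2.0))
        noise = rng.standard_normal((h, w))
        sm = gaussian_filter(noise, sigma, mode="reflect")
        lo, hi = sm.min(), sm.max()
        span = hi - lo if hi > lo else 1.0
        img = (0.1 + 0.8 * (sm - lo) / span) * peak
    elif spec.kind == "step_edge":
        col = int(p.get("edge_col", w // 2))
        lo = float(p.get("low", 0.2 * peak))
        hi = float(p.get("high", 0.8 * peak))
        img = np.where(jj < col, lo, hi)
    else:  # pragma: no cover - guarded by FixtureSpec
        raise ValueError(spec.kind)
    return np.clip(np.rint(img), 0, peak).astype(np.uint8 if bit_depth <= 8 else np.uint16)


def _separated_centers(rng, h: int, w: int, k: int, min_dist: float, margin_frac: float = 0.15):
    """Rejection-sample k blob centres pairwise at least min_dist apart."""
    mi, mj = h * margin_frac, w * margin_frac
    centers: List[tuple] = []
    for _ in range(10000):
        if len(centers) == k:
            break
        ci = rng.uniform(mi, h - mi)
        cj = rng.uniform(mj, w - mj)
        if all((ci - a) ** 2 + (cj - b) ** 2 >= min_dist**2 for a, b in centers):
            centers.append((ci, cj))
    if len(centers) < k:
        raise ValueError(f"could not place {k} blobs at separation {min_dist} in {h}x{w}")
    return centers


def generate_corpus(specs: Sequence[FixtureSpec], out_dir: str | Path, bit_depth: int = 8) -> dict:
    """Write every spec as a PNG plus a JSON manifest; returns the manifest."""
    import imageio.v3 as iio

    if not specs:
        raise ValueError("generate_corpus needs at least one spec")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, spec in enumerate(specs):
        img = generate(spec, bit_depth=bit_depth)
        name = f"{i:04d}_{spec.kind}_s{spec.seed}.png"
        iio.imwrite(out_dir / name, img)
        entries.append({"file": name, "spec": spec.to_dict()})
    manifest = {"bit_depth": bit_depth, "images": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def default_corpus_specs(n: int, base_seed: int = 0, height: int = 64, width: int = 64) -> List[FixtureSpec]:
    """A mixed textured corpus: smooth noise, blobs, sinusoids, checkers."""
    kinds = ["smooth_noise", "gaussian_blobs", "sinusoid", "checkerboard"]
    specs = []
    for i in range(n):
        kind = kinds[i % len(kinds)]
        specs.append(FixtureSpec(kind=kind, height=height, width=width, seed=base_seed + i))
    return specs
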