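"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own computation paths: the
upscaling oracle evaluates the separable cubic kernel row-vector x
neighbourhood x column-vector product in exact rational arithmetic per
output pixel, and the convolution / distance oracles are plain nested
loops.
"""

from fractions import Fraction

import numpy as np


def kernel_rational(omega) -> Fraction:
    """Piecewise cubic kernel as an exact rational, even extension."""
    w = abs(Fraction(omega))
    if w < 1:
        return 1 - 2 * w * w + w**3
    if w < 2:
        return 4 - 8 * w + 5 * w * w - w**3
    return Fraction(0)


def rational_upscale_interior(img: np.ndarray) -> dict:
    """Direct separable evaluation at the 16 subcell midpoints.

    For every interior anchor (i, j) (stencil fully inside the image)
    and subcell (a, b), computes row-vector x 4x4 block x column-vector
    with exact Fractions at v = (2a+1)/8, u = (2b+1)/8.  Returns
    {(output_row, output_col): Fraction value}.
    """
    h, w = img.shape
    out = {}
    for i in range(1, h - 2):
        for j in range(1, w - 2):
            block = img[i - 1 : i + 3, j - 1 : j + 3]
            for a in range(4):
                for b in range(4):
                    v = Fraction(2 * a + 1, 8)
                    u = Fraction(2 * b + 1, 8)
                    row = [kernel_rational(1 + v), kernel_rational(v),
                           kernel_rational(1 - v), kernel_rational(2 - v)]
                    col = [kernel_rational(1 + u), kernel_rational(u),
                           kernel_rational(1 - u), kernel_rational(2 - u)]
                    val = Fraction(0)
                    for r in range(4):
                        for c in range(4):
                            val += row[r] * Fraction(int(block[r, c])) * col[c]
                    out[(4 * i + a, 4 * j + b)] = val
    return out


def loop_conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nested-loop 'same' zero-padded cross-correlation (N, C, H, W)."""
    n, cin, h, wd = x.shape
    k, _, f, _ = w.shape
    pad = f // 2
    out = np.zeros((n, k, h, wd))
    for ni in range(n):
        for ki in range(k):
            for yi in range(h):
                for xi in range(wd):
                    acc = b[ki]
                    for ci in range(cin):
                        for fy in range(f):
                            for fx in range(f):
                                sy, sx = yi + fy - pad, xi + fx - pad
                                if 0 <= sy < h and 0 <= sx < wd:
                                    acc += x[ni, ci, sy, sx] * w[ki, ci, fy, fx]
                    out[ni, ki, yi, xi] = acc
    return out


def brute_force_mean_min_distance(ds: np.ndarray, dt: np.ndarray) -> float:
    """Double-loop mean-over-rows of min Euclidean distance to any row of dt."""
    total = 0.0
    for i in range(ds.shape[0]):
        best = None
        for j in range(dt.shape[0]):
            d = float(np.sqrt(np.sum((ds[i] - dt[j]) ** 2)))
            best = d if best is None else min(best, d)
        total += best
    return total / ds.shape[0]
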