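"""Template-bank upscaling: exactness, symmetry and operation counts."""

from fractions import Fraction

import numpy as np
import pytest

from _oracles import rational_upscale_interior
from medisr.templates import TEMPLATE_DENOMINATOR
from medisr.upscale import count_ops, round_half_away, upscale4, upscale4_numerators


def interior_mask(h, w):
    """Output pixels whose paper-grid stencil never touches padding."""
    mask = np.zeros((4 * h, 4 * w), dtype=bool)
    mask[4:4 * (h - 2), 4:4 * (w - 2)] = True
    return mask


def test_constant_image_is_preserved(bank):
    img = np.full((6, 7), 113, dtype=np.int64)
    out = upscale4(img, bank)
    assert out.shape == (24, 28)
    assert np.all(out == 113)
    fimg = np.full((5, 5), 0.37)
    fout = upscale4(fimg, bank)
    assert np.allclose(fout, 0.37)


def test_small_image_rejected(bank):
    with pytest.raises(ValueError):
        upscale4(np.zeros((3, 8), dtype=np.int64), bank)


def test_unknown_border_rejected(bank):
    with pytest.raises(ValueError):
        upscale4(np.zeros((8, 8), dtype=np.int64), bank, border="wrap")


def effective_offset(mid: Fraction) -> Fraction:
    """First moment of the 1-D kernel weights at a midpoint offset.

    The a = -1 cubic kernel has a nonzero first moment (it is exact for
    constants but not for linear polynomials — that property belongs to
    the a = -1/2 variant), so an affine ramp is mapped to the same ramp
    evaluated at this *effective* offset rather than at the nominal one.
    """
    from medisr.templates import cubic_kernel

    weights = [cubic_kernel(1 + mid), cubic_kernel(mid), cubic_kernel(1 - mid), cubic_kernel(2 - mid)]
    return sum(wt * (r - 1) for r, wt in enumerate(weights))


def test_affine_ramp_maps_to_ramp_at_effective_offsets(bank):
    # exact rational identity: on an affine image the separable
    # contraction returns alpha*(i + phi(v)) + beta*(j + phi(u)) + gamma
    # where phi is the kernel's first moment at each midpoint
    h = w = 6
    alpha, beta, gamma = 8, 4, 16
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    img = (alpha * ii + beta * jj + gamma).astype(np.int64)
    nums = upscale4_numerators(img, bank)
    phi = {a: effective_offset(Fraction(2 * a + 1, 8)) for a in range(4)}
    assert phi[0] == Fraction(106, 512)  # not the nominal 1/8
    for i in range(1, h - 2):
        for j in range(1, w - 2):
            for a in range(4):
                for b in range(4):
                    expect = (alpha * (i + phi[a]) + beta * (j + phi[b]) + gamma) * TEMPLATE_DENOMINATOR
                    assert expect.denominator == 1
                    assert nums[4 * i + a, 4 * j + b] == int(expect)


@pytest.mark.parametrize("trial", range(20))
def test_oracle_equivalence_random_images(bank, trial):
    rng = np.random.default_rng(1000 + trial)
    img = rng.integers(0, 256, (8, 8)).astype(np.int64)
    nums = upscale4_numerators(img, bank, grid="paper")
    for (r, c), frac in rational_upscale_interior(img).items():
        exact = frac * TEMPLATE_DENOMINATOR
        assert exact.denominator == 1
        assert nums[r, c] == int(exact), f"mismatch at output ({r}, {c})"


def centered_interior(h, w):
    """Output pixels whose centred-grid stencil never touches padding."""
    mask = np.zeros((4 * h, 4 * w), dtype=bool)
    mask[8:4 * h - 8, 8:4 * w - 8] = True
    return mask


def test_horizontal_flip_equivariance(bank, rng):
    # the bank maps template u -> 1-u under a flip; on the centre-aligned
    # grid (symmetric about the image centre) this is plain reversal
    img = rng.integers(0, 256, (8, 8)).astype(np.int64)
    a = upscale4_numerators(img, bank, grid="centered")
    b = upscale4_numerators(img[:, ::-1].copy(), bank, grid="centered")
    m = centered_interior(*img.shape)
    assert np.array_equal(a[m], b[:, ::-1][m])


def test_vertical_flip_equivariance(bank, rng):
    img = rng.integers(0, 256, (9, 8)).astype(np.int64)
    a = upscale4_numerators(img, bank, grid="centered")
    b = upscale4_numerators(img[::-1].copy(), bank, grid="centered")
    m = centered_interior(*img.shape)
    assert np.array_equal(a[m], b[::-1][m])


def test_paper_grid_flip_equivariance_up_to_lattice_shift(bank, rng):
    # the paper grid sits +1/8 LR pixel off-centre, so a flip shifts the
    # sampled lattice by one LR pixel (4 HR pixels)
    img = rng.integers(0, 256, (8, 8)).astype(np.int64)
    a = upscale4_numerators(img, bank, grid="paper")
    b = upscale4_numerators(img[:, ::-1].copy(), bank, grid="paper")[:, ::-1]
    assert np.array_equal(a[8:-8, 8:-12], b[8:-8, 12:-8])


def test_centered_grid_is_exact_translation_of_paper_grid(bank, rng):
    img = rng.integers(0, 256, (10, 12)).astype(np.int64)
    paper = upscale4_numerators(img, bank, grid="paper")
    centered = upscale4_numerators(img, bank, grid="centered")
    # away from borders the two conventions differ by 2 HR pixels
    assert np.array_equal(paper[8:-12, 8:-12], centered[10:-10, 10:-10])


def test_round_half_away_from_zero():
    d = TEMPLATE_DENOMINATOR
    nums = np.array([0, d // 2, d // 2 - 1, -d // 2, 3 * d, -3 * d - d // 2])
    assert round_half_away(nums).tolist() == [0, 1, 0, -1, 3, -4]


def test_output_range_with_clamping(bank):
    # checkerboard maximises overshoot from the negative lobes
    img = np.zeros((8, 8), dtype=np.int64)
    img[::2, 1::2] = 255
    img[1::2, ::2] = 255
    out = upscale4(img, bank, clamp=True)
    assert out.min() >= 0 and out.max() <= 255
    # without clamping, overshoot is bounded by the negative-lobe mass
    nums = upscale4_numerators(img, bank)
    bound = max(np.abs(t.numerators).sum() for t in bank) * 255
    assert np.abs(nums).max() <= bound


def test_overshoot_actually_occurs_unclamped(bank):
    img = np.zeros((8, 8), dtype=np.int64)
    img[:, 4:] = 255
    nums = upscale4_numerators(img, bank)
    vals = nums / TEMPLATE_DENOMINATOR
    assert vals.min() < 0 or vals.max() > 255


def test_reflect_border_differs_from_replicate_only_near_edges(bank, rng):
    img = rng.integers(0, 256, (8, 8)).astype(np.int64)
    a = upscale4_numerators(img, bank, border="replicate")
    b = upscale4_numerators(img, bank, border="reflect")
    m = interior_mask(*img.shape)
    assert np.array_equal(a[m], b[m])


def test_count_ops_per_pixel(bank):
    img = np.arange(25, dtype=np.int64).reshape(5, 5) * 7 % 256
    ops = count_ops(img, bank)
    assert ops.int_mul == 16
    assert ops.int_add == 15
    assert ops.int_div == 1
    assert ops.float_add == 0
    assert ops.float_mul == 0


def test_count_ops_requires_integers(bank):
    with pytest.raises(TypeError):
        count_ops(np.zeros((5, 5)), bank)
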