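"""Exact derivation of the 16 integer bicubic interpolation templates.

Cubic convolution interpolation (the a = -1 piecewise-cubic kernel)
reconstructs an intermediate pixel value from its 4x4 integer-pixel
neighbourhood.  For a fixed fractional offset ``(u, v)`` inside the unit
cell -- ``u`` along columns, ``v`` along rows -- the separable kernel
collapses into a single 4x4 weight stencil

    T[r, c] = S(row_factor_r(v)) * S(col_factor_c(u)),

with row factors ``(1+v, v, 1-v, 2-v)`` and column factors
``(1+u, u, 1-u, 2-u)``.  At the 16 quarter-cell midpoints
``u, v in {1/8, 3/8, 5/8, 7/8}`` every weight is an exact multiple of
``1/2^18``: each one-dimensional kernel value is an integer over 512 and
the stencil is the outer product of two such vectors.  Storing the
integer numerators turns x4 bicubic upscaling into pure integer
arithmetic (16 multiplies, 15 adds, 1 division per output pixel).

Everything in this module is computed with :class:`fractions.Fraction`;
floating point never enters the derivation, so the templates are
bit-exact and reproducible on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Tuple

import numpy as np

#: Common denominator of every one-dimensional kernel weight at the
#: quarter-cell midpoints (2 ** 9).
KERNEL_DENOMINATOR = 512

#: Common denominator of every 2-D template entry (512 ** 2 == 2 ** 18).
TEMPLATE_DENOMINATOR = 262144

#: The quarter-interval midpoints used to discretize the unit cell.
MIDPOINTS = (Fraction(1, 8), Fraction(3, 8), Fraction(5, 8), Fraction(7, 8))


def cubic_kernel(omega: Fraction | int | str) -> Fraction:
    """Evaluate the cubic convolution kernel S(omega) exactly.

    Parameters
    ----------
    omega : Fraction-like, >= 0
        Distance from the interpolation point, as an exact rational.
        Negative arguments are rejected; the kernel is even, so callers
        supply ``abs(omega)``.

    Returns
    -------
    Fraction
        ``1 - 2*w^2 + w^3`` on ``[0, 1)``, ``4 - 8*w + 5*w^2 - w^3`` on
        ``[1, 2)`` and ``0`` for ``w >= 2``, as an exact rational.
    """
    w = Fraction(omega)
    if w < 0:
        raise ValueError(f"cubic_kernel requires omega >= 0, got {w}")
    if w < 1:
        return 1 - 2 * w * w + w * w * w
    if w < 2:
        return 4 - 8 * w + 5 * w * w - w * w * w
    return Fraction(0)


def kernel_numerator(omega: Fraction) -> int:
    """S(omega) scaled to an integer over :data:`KERNEL_DENOMINATOR`.

    Raises if the exact value is not a multiple of 1/512 (only offsets
    with denominator dividing 8 produce such values).
    """
    value = cubic_kernel(omega) * KERNEL_DENOMINATOR
    if value.denominator != 1:
        raise ValueError(
            f"S({omega}) = {cubic_kernel(omega)} is not an integer over {KERNEL_DENOMINATOR}"
        )
    return int(value)


def kernel_vector(offset: Fraction) -> Tuple[int, int, int, int]:
    """The four 1-D weights for fractional offset ``x``, over 512.

    Order follows the 4x4 neighbourhood: ``(S(1+x), S(x), S(1-x), S(2-x))``
    weighting pixels at relative positions -1, 0, +1, +2.
    """
    x = Fraction(offset)
    if not (0 < x < 1):
        raise ValueError(f"offset must lie in (0, 1), got {x}")
    return (
        kernel_numerator(1 + x),
        kernel_numerator(x),
        kernel_numerator(1 - x),
        kernel_numerator(2 - x),
    )


@dataclass(frozen=True)
class Template:
    """One discretized bicubic stencil: a 4x4 integer numerator matrix.

    ``numerators[r, c] / 2^18`` is the weight applied to the input pixel
    at relative position ``(r - 1, c - 1)`` from the anchor pixel, i.e.
    rows ``i-1 .. i+2`` and columns ``j-1 .. j+2``.
    """

    index: int
    u_mid: Fraction
    v_mid: Fraction
    numerators: np.ndarray = field(repr=False)
    denominator: int = TEMPLATE_DENOMINATOR

    def __post_init__(self) -> None:
        num = np.asarray(self.numerators, dtype=np.int64)
        if num.shape != (4, 4):
            raise ValueError(f"template numerators must be 4x4, got {num.shape}")
        object.__setattr__(self, "numerators", num)
        total = int(num.sum())
        if total != self.denominator:
            raise ValueError(
                f"template {self.index} numerators sum to {total}, expected {self.denominator}"
            )

    def as_float(self) -> np.ndarray:
        """The stencil as float64 weights summing to 1."""
        return self.numerators.astype(np.float64) / self.denominator


def derive_template(u: Fraction | str, v: Fraction | str, index: int = 0) -> Template:
    """Derive the exact integer template for fractional offsets (u, v).

    ``u`` is the offset along the second (column) axis, ``v`` along the
    first (row) axis.  The stencil is the outer product of the two 1-D
    kernel vectors: rows carry the v-dependent factor, columns the
    u-dependent factor.
    """
    u = Fraction(u)
    v = Fraction(v)
    row = kernel_vector(v)
    col = kernel_vector(u)
    numerators = np.outer(np.array(row, dtype=np.int64), np.array(col, dtype=np.int64))
    return Template(index=index, u_mid=u, v_mid=v, numerators=numerators)


@dataclass(frozen=True)
class TemplateBank:
    """The ordered bank of 16 templates T1..T16.

    Ordering is v-interval major, u-interval minor: T1 = (u=1/8, v=1/8),
    T2 = (u=3/8, v=1/8), ..., T5 = (u=1/8, v=3/8), ..., T16 = (u=7/8,
    v=7/8).  Banks are indexed 1-based (``bank[1]`` .. ``bank[16]``) to
    match the template numbering.
    """

    templates: Tuple[Template, ...]

    def __post_init__(self) -> None:
        if len(self.templates) != 16:
            raise ValueError(f"a template bank holds 16 templates, got {len(self.templates)}")

    def __getitem__(self, index: int) -> Template:
        if not 1 <= index <= 16:
            raise IndexError(f"template index must be 1..16, got {index}")
        return self.templates[index - 1]

    def __iter__(self):
        return iter(self.templates)

    def by_offsets(self, u: Fraction, v: Fraction) -> Template:
        """Look up the template for exact midpoint offsets (u, v)."""
        for t in self.templates:
            if t.u_mid == u and t.v_mid == v:
                return t
        raise KeyError(f"no template with midpoints u={u}, v={v}")

    def stack_float(self) -> np.ndarray:
        """All 16 stencils as a (16, 4, 4) float64 array of unit-sum weights."""
        return np.stack([t.as_float() for t in self.templates])

    def stack_int(self) -> np.ndarray:
        """All 16 numerator matrices as a (16, 4, 4) int64 array."""
        return np.stack([t.numerators for t in self.templates])

    def to_dict(self) -> dict:
        return {
            "denominator": TEMPLATE_DENOMINATOR,
            "templates": [
                {
                    "index": t.index,
                    "u": str(t.u_mid),
                    "v": str(t.v_mid),
                    "numerators": t.numerators.tolist(),
                }
                for t in self.templates
            ],
        }


def build_template_bank() -> TemplateBank:
    """Build all 16 templates at the quarter-cell midpoints.

    Index k = 1..16 runs over v in {1/8, 3/8, 5/8, 7/8} (outer) and u in
    the same set (inner).
    """
    templates: List[Template] = []
    k = 0
    for v in MIDPOINTS:
        for u in MIDPOINTS:
            k += 1
            templates.append(derive_template(u, v, index=k))
    return TemplateBank(templates=tuple(templates))


@dataclass(frozen=True)
class Discrepancy:
    """One cell where the derivation and a printed transcription differ."""

    template_index: int
    row: int
    col: int
    derived: int
    printed: int


def verify_against_printed(
    bank: TemplateBank, printed: Mapping[int, "np.ndarray | list"]
) -> List[Discrepancy]:
    """Compare derived templates against a transcription of published values.

    Parameters
    ----------
    bank : TemplateBank
        The derived bank.
    printed : mapping of template index -> 4x4 integer matrix
        Hand-transcribed numerator values to check against.

    Returns
    -------
    list of Discrepancy
        Every (template, cell) where derivation and transcription
        disagree; empty when they agree everywhere (or ``printed`` is
        empty).  Transcription typos show up here rather than being
        silently replicated.
    """
    report: List[Discrepancy] = []
    for idx in sorted(printed):
        ref = np.asarray(printed[idx], dtype=np.int64)
        if ref.shape != (4, 4):
            raise ValueError(f"printed template {idx} must be 4x4, got {ref.shape}")
        derived = bank[idx].numerators
        for r, c in zip(*np.nonzero(derived != ref)):
            report.append(
                Discrepancy(
                    template_index=idx,
                    row=int(r),
                    col=int(c),
                    derived=int(derived[r, c]),
                    printed=int(ref[r, c]),
                )
            )
    return report
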