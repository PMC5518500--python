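"""Hand-transcribed published values of the 16 bicubic templates.

These integer matrices were transcribed from the published solution
table (numerators over 2^18) and serve as a regression reference for
:func:`medisr.templates.verify_against_printed`.  They are data, not a
derivation: the printed table contains one known typo — template 11,
cell (1, 1), prints 2205 where the kernel derivation yields
S(13/8)^2 * 2^18 = (-45)^2 * 512^2 / 512^2... i.e. 45^2 = 2025 — and the
transcription reproduces the typo faithfully so the discrepancy report
documents it.
"""

from __future__ import annotations

import numpy as np

PRINTED_DENOMINATOR = 262144

#: Cells where the published table is known to disagree with the exact
#: derivation: {(template_index, row, col): (printed, derived)}.
KNOWN_TYPOS = {(11, 0, 0): (2205, 2025)}

_RAW = {
    1: [
        [2401, -24353, -3479, 343],
        [-24353, 247009, 35287, -3479],
        [-3479, 35287, 5041, -497],
        [343, -3479, -497, 49],
    ],
    2: [
        [3675, -19355, -11613, 2205],
        [-37275, 196315, 117789, -22365],
        [-5325, 28045, 16827, -3195],
        [525, -2765, -1659, 315],
    ],
    3: [
        [2205, -11613, -19355, 3675],
        [-22365, 117789, 196315, -37275],
        [-3195, 16827, 28045, -5325],
        [315, -1659, -2765, 525],
    ],
    4: [
        [343, -3479, -24353, 2401],
        [-3479, 35287, 247009, -24353],
        [-497, 5041, 35287, -3479],
        [49, -497, -3479, 343],
    ],
    5: [
        [3675, -37275, -5325, 525],
        [-19355, 196315, 28045, -2765],
        [-11613, 117789, 16827, -1659],
        [2205, -22365, -3195, 315],
    ],
    6: [
        [5625, -29625, -17775, 3375],
        [-29625, 156025, 93615, -17775],
        [-17775, 93615, 56169, -10665],
        [3375, -17775, -10665, 2025],
    ],
    7: [
        [3375, -17775, -29625, 5625],
        [-17775, 93615, 156025, -29625],
        [-10665, 56169, 93615, -17775],
        [2025, -10665, -17775, 3375],
    ],
    8: [
        [525, -5325, -37275, 3675],
        [-2765, 28045, 196315, -19355],
        [-1659, 16827, 117789, -11613],
        [315, -3195, -22365, 2205],
    ],
    9: [
        [2205, -22365, -3195, 315],
        [-11613, 117789, 16827, -1659],
        [-19355, 196315, 28045, -2765],
        [3675, -37275, -5325, 525],
    ],
    10: [
        [3375, -17775, -10665, 2025],
        [-17775, 93615, 56169, -10665],
        [-29625, 156025, 93615, -17775],
        [5625, -29625, -17775, 3375],
    ],
    11: [
        [2205, -10665, -17775, 3375],
        [-10665, 56169, 93615, -17775],
        [-17775, 93615, 156025, -29625],
        [3375, -17775, -29625, 5625],
    ],
    12: [
        [315, -3195, -22365, 2205],
        [-1659, 16827, 117789, -11613],
        [-2765, 28045, 196315, -19355],
        [525, -5325, -37275, 3675],
    ],
    13: [
        [343, -3479, -497, 49],
        [-3479, 35287, 5041, -497],
        [-24353, 247009, 35287, -3479],
        [2401, -24353, -3479, 343],
    ],
    14: [
        [525, -2765, -1659, 315],
        [-5325, 28045, 16827, -3195],
        [-37275, 196315, 117789, -22365],
        [3675, -19355, -11613, 2205],
    ],
    15: [
        [315, -1659, -2765, 525],
        [-3195, 16827, 28045, -5325],
        [-22365, 117789, 196315, -37275],
        [2205, -11613, -19355, 3675],
    ],
    16: [
        [49, -497, -3479, 343],
        [-497, 5041, 35287, -3479],
        [-3479, 35287, 247009, -24353],
        [343, -3479, -24353, 2401],
    ],
}

PRINTED_TEMPLATES = {k: np.array(v, dtype=np.int64) for k, v in _RAW.items()}
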