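"""Published reference tables from a six-variety rough-rice e-nose study.

A PEN3-style ten-sensor array measured the headspace volatiles of six rough
rice (paddy) varieties, 20 samples each.  The study printed the PCA
eigenvalue spectrum of the D_ave feature matrix, the full upper-triangular
table of pairwise PC dispersion ratios (Wilks lambda values), and the
test-set confusion matrices of a PNN classifier run on the PC1/PC2 and
PC1/PC5 score pairs at spread 4e-5.  The raw sensor recordings were not
deposited, so these printed tables are the only numeric ground truth
available; they serve as inputs for arithmetic-level verification of this
package (explained-variance percentages, pair selection, accuracy
computation).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RICE_EIGENVALUES",
    "RICE_DISPERSION_RATIOS",
    "RICE_CLASSES",
    "RICE_CONFUSION_PC1_PC2",
    "RICE_CONFUSION_PC1_PC5",
    "dispersion_ratio_table",
]

#: PCA eigenvalues of the 120 x 10 D_ave feature matrix, descending
RICE_EIGENVALUES = np.array(
    [
        9.460e-5,
        2.9085e-7,
        8.0030e-8,
        3.8928e-8,
        1.9657e-8,
        3.7732e-9,
        8.2980e-10,
        4.9310e-10,
        1.8386e-10,
        8.4961e-11,
    ]
)

#: upper-triangular dispersion-ratio table; row PC i (1..9), columns PC j > i
_RATIO_ROWS = {
    1: [0.1441, 0.1855, 0.1687, 0.1254, 0.1709, 0.1877, 0.1552, 0.1407, 0.1569],
    2: [0.5154, 0.4351, 0.3127, 0.3563, 0.4921, 0.4793, 0.4642, 0.4855],
    3: [0.6940, 0.5111, 0.5122, 0.7981, 0.7470, 0.7650, 0.7846],
    4: [0.4195, 0.5632, 0.6848, 0.7219, 0.7435, 0.7360],
    5: [0.3298, 0.4631, 0.4728, 0.4979, 0.5204],
    6: [0.7126, 0.6931, 0.7189, 0.6781],
    7: [0.9207, 0.9848, 0.8886],
    8: [0.9332, 0.9511],
    9: [0.9562],
}

RICE_DISPERSION_RATIOS: dict[tuple[int, int], float] = {
    (i, i + 1 + k): v for i, row in _RATIO_ROWS.items() for k, v in enumerate(row)
}


def dispersion_ratio_table() -> dict[tuple[int, int], float]:
    """The 45 printed pairwise dispersion ratios keyed by (i, j), i < j."""
    return dict(RICE_DISPERSION_RATIOS)


#: rough-rice variety abbreviations, in the printed table order
RICE_CLASSES = ["P36", "WT025", "XW13", "YPX", "YY122", "ZX1"]

#: PNN test-set confusion matrix, PC1/PC2 inputs, spread 4e-5
RICE_CONFUSION_PC1_PC2 = np.array(
    [
        [5, 0, 0, 0, 0, 0],
        [0, 4, 0, 0, 1, 0],
        [0, 0, 5, 0, 0, 0],
        [0, 0, 0, 5, 0, 0],
        [0, 0, 2, 0, 3, 0],
        [0, 0, 0, 0, 0, 5],
    ]
)

#: PNN test-set confusion matrix, PC1/PC5 inputs, spread 4e-5
RICE_CONFUSION_PC1_PC5 = np.array(
    [
        [5, 0, 0, 0, 0, 0],
        [0, 4, 0, 0, 0, 1],
        [0, 0, 5, 0, 0, 0],
        [0, 0, 0, 5, 0, 0],
        [0, 0, 0, 0, 5, 0],
        [0, 0, 0, 0, 0, 5],
    ]
)
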