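"""Background amino-acid composition shared by profiles and fixture generators.

The table is the Robinson & Robinson average composition of globular
proteins, renormalized to sum to exactly 1.
"""

from __future__ import annotations

import numpy as np

from .reference import AMINO_ACIDS

_RAW = {
    "A": 0.0785, "R": 0.0512, "N": 0.0448, "D": 0.0536, "C": 0.0168,
    "Q": 0.0426, "E": 0.0633, "G": 0.0735, "H": 0.0227, "I": 0.0529,
    "L": 0.0935, "K": 0.0592, "M": 0.0224, "F": 0.0405, "P": 0.0497,
    "S": 0.0715, "T": 0.0571, "W": 0.0110, "Y": 0.0319, "V": 0.0644,
}

_total = sum(_RAW.values())

#: residue -> background frequency, ordered as :data:`AMINO_ACIDS`.
BACKGROUND_FREQUENCIES = {aa: _RAW[aa] / _total for aa in AMINO_ACIDS}

#: numpy view of the background, ordered as :data:`AMINO_ACIDS`.
BACKGROUND_VECTOR = np.array([BACKGROUND_FREQUENCIES[aa] for aa in AMINO_ACIDS])

#: residue -> index into :data:`AMINO_ACIDS`.
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
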