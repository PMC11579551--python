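"""Molecular formulas, monoisotopic masses and electrospray adduct m/z values.

Used to turn a proposed product formula into the m/z an HRMS instrument would
report, e.g. the protonated ion of anhydrosclerotinin B (C12H12O4) at
m/z 221.0808.  Protonation adds the mass of a bare proton (1.00727646 Da),
not of a hydrogen atom — the electron stays behind.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections import Counter

from .errors import ParseError, ValidationError

#: Monoisotopic atomic masses (Da), pinned to 8 decimal places.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

#: Mass of a proton (Da).
PROTON_MASS = 1.00727646

#: Adduct label -> m/z offset relative to the neutral monoisotopic mass.
ADDUCTS = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M+Na]+": 22.98922,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element symbol -> count; immutable and hashable by its formatted string."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "MolecularFormula":
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ParseError(f"unknown element symbol {el!r}")
            if n < 0:
                raise ValidationError(f"negative count for element {el}")
        return cls(tuple(sorted((el, n) for el, n in counts.items() if n > 0)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = Counter(self.as_dict())
        merged.update(other.as_dict())
        return MolecularFormula.from_dict(dict(merged))

    def hill_format(self) -> str:
        """Hill notation: C first, H second, then remaining elements alphabetically."""
        counts = self.as_dict()
        order = [el for el in ("C", "H") if el in counts]
        order += sorted(el for el in counts if el not in ("C", "H"))
        return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order)

    def __str__(self) -> str:
        return self.hill_format()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``C12H12O4`` (implicit count 1)."""
    text = text.strip()
    if not text:
        raise ParseError("empty formula string")
    counts: Counter[str] = Counter()
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ParseError(f"unparseable formula fragment {text[pos:m.start()]!r}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ParseError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] += int(num) if num else 1
        pos = m.end()
    if pos != len(text):
        raise ParseError(f"unparseable formula fragment {text[pos:]!r}")
    return MolecularFormula.from_dict(dict(counts))


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Sum of monoisotopic atomic masses, in Da."""
    counts = formula.as_dict()
    if not counts:
        raise ValidationError("cannot compute the mass of an empty formula")
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in counts.items())


def adduct_mz(formula: MolecularFormula, adduct: str) -> float:
    """m/z of a singly charged adduct ion ([M+H]+, [M-H]-, [M+Na]+)."""
    key = adduct.replace("−", "-")  # tolerate unicode minus
    if key not in ADDUCTS:
        raise ValidationError(
            f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}"
        )
    return monoisotopic_mass(formula) + ADDUCTS[key]
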