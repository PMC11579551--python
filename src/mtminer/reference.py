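"""Reference annotation of the CitS MT domain and the catalog of characterized synthases.

The coordinate system used throughout mtminer is *CitS numbering*: 1-based
residue indices of the citrinin synthase PksCT/CitS.  The crystal structure of
its C-methyltransferase (MT) domain defines 17 substrate-binding-pocket
residues spanning CitS 1938-2153, two of which (His2067/Glu2093) form the
catalytic dyad.  Reading those 17 positions out of any candidate MT domain
gives its active-site *fingerprint*, the quantity every downstream module
works with.

The catalog pairs each characterized synthase's fingerprint with its
*methylation pattern*: how many chain-elongation rounds the synthase performs
and which of them receive an alpha-methyl group.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import ParseError, ValidationError

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GAP = "-"

ROLE_POCKET = "pocket"
ROLE_DYAD = "catalytic_dyad"

#: Number of substrate-binding-pocket positions in the CitS MT domain.
POCKET_SIZE = 17

#: CitS numbering of the catalytic dyad (His2067, Glu2093).
DYAD = ((2067, "H"), (2093, "E"))


@dataclass(frozen=True)
class PocketPosition:
    """One annotated substrate-binding-pocket residue in CitS numbering."""

    cits_position: int
    reference_residue: str
    role: str = ROLE_POCKET


@dataclass
class ReferenceDomain:
    """The reference MT domain sequence with its pocket annotation.

    ``numbering_offset`` is the CitS residue number of the first sequence
    character, so CitS position ``p`` corresponds to sequence index
    ``p - numbering_offset`` (0-based).
    """

    name: str
    sequence: str
    numbering_offset: int
    pocket: list[PocketPosition] = field(default_factory=list)

    @property
    def numbering_end(self) -> int:
        return self.numbering_offset + len(self.sequence) - 1

    def index_of(self, cits_position: int) -> int:
        """0-based sequence index of a CitS position; raises if out of range."""
        idx = cits_position - self.numbering_offset
        if not 0 <= idx < len(self.sequence):
            raise ValidationError(
                f"CitS position {cits_position} outside reference range "
                f"[{self.numbering_offset}, {self.numbering_end}]"
            )
        return idx

    def residue_at(self, cits_position: int) -> str:
        return self.sequence[self.index_of(cits_position)]

    def pocket_positions(self) -> list[int]:
        return [p.cits_position for p in self.pocket]


@dataclass(frozen=True)
class MethylationPattern:
    """Chain-length program of a synthase: extension count and methylated rounds.

    ``n_extensions`` counts chain-elongation (malonyl condensation) rounds, so
    a pentaketide corresponds to ``n_extensions=4``.  ``methylated_rounds``
    holds the 1-based indices of the rounds in which the MT domain acts.
    """

    n_extensions: int
    methylated_rounds: frozenset[int]

    def __post_init__(self):
        if self.n_extensions < 1:
            raise ValidationError("n_extensions must be >= 1")
        rounds = frozenset(self.methylated_rounds)
        object.__setattr__(self, "methylated_rounds", rounds)
        if not rounds <= set(range(1, self.n_extensions + 1)):
            raise ValidationError(
                f"methylated_rounds {sorted(rounds)} not a subset of "
                f"1..{self.n_extensions}"
            )

    def encode_rounds(self) -> str:
        return "+".join(str(r) for r in sorted(self.methylated_rounds))


@dataclass(frozen=True)
class KnownSynthase:
    """Catalog entry: a characterized synthase with fingerprint and pattern."""

    name: str
    product_name: str
    pattern: MethylationPattern
    fingerprint: str
    group_label: str = ""


@dataclass(frozen=True)
class CheckResult:
    check: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[CheckResult] = field(default_factory=list)

    def add(self, check: str, passed: bool, detail: str = "") -> None:
        self.checks.append(CheckResult(check, passed, detail))

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __getitem__(self, check: str) -> CheckResult:
        for c in self.checks:
            if c.check == check:
                return c
        raise KeyError(check)


def validate_reference(ref: ReferenceDomain) -> ValidationReport:
    """Run every reference-annotation check; failures are report entries, never raises."""
    report = ValidationReport()

    in_range = all(
        ref.numbering_offset <= p.cits_position <= ref.numbering_end for p in ref.pocket
    )
    report.add("positions_in_range", in_range)

    increasing = all(
        a.cits_position < b.cits_position for a, b in zip(ref.pocket, ref.pocket[1:])
    )
    report.add("positions_strictly_increasing", increasing)

    alphabet_ok = all(p.reference_residue in AMINO_ACIDS for p in ref.pocket)
    report.add("residues_in_alphabet", alphabet_ok)

    if in_range:
        mismatches = [
            p.cits_position
            for p in ref.pocket
            if ref.residue_at(p.cits_position) != p.reference_residue
        ]
        report.add(
            "sequence_matches_annotation",
            not mismatches,
            "" if not mismatches else f"mismatch at {mismatches}",
        )
    else:
        report.add("sequence_matches_annotation", False, "positions out of range")

    report.add(
        "pocket_count",
        len(ref.pocket) == POCKET_SIZE,
        f"found {len(ref.pocket)}, expected {POCKET_SIZE}",
    )

    dyad = [p for p in ref.pocket if p.role == ROLE_DYAD]
    report.add("dyad_count", len(dyad) == 2, f"found {len(dyad)} dyad positions")
    dyad_map = {p.cits_position: p.reference_residue for p in dyad}
    report.add(
        "dyad_identity",
        all(dyad_map.get(pos) == aa for pos, aa in DYAD),
        f"expected His{DYAD[0][0]}/Glu{DYAD[1][0]}, found "
        + ", ".join(f"{aa}{pos}" for pos, aa in sorted(dyad_map.items())),
    )
    return report


def _require_valid(ref: ReferenceDomain) -> None:
    report = validate_reference(ref)
    hard = (
        "positions_in_range",
        "positions_strictly_increasing",
        "residues_in_alphabet",
        "sequence_matches_annotation",
    )
    failed = [c for c in report.checks if c.check in hard and not c.passed]
    if failed:
        raise ValidationError(
            "invalid reference: " + "; ".join(f"{c.check} {c.detail}".strip() for c in failed)
        )


def reference_self_fingerprint(ref: ReferenceDomain) -> str:
    """The reference's own fingerprint: annotated residues in pocket order."""
    _require_valid(ref)
    return "".join(p.reference_residue for p in ref.pocket)


# ---------------------------------------------------------------------------
# Reference file I/O
#
# Format: '#' comments; "key = value" header lines (name, numbering_offset);
# a FASTA-style '>' line starting the sequence block; a "[positions]" line
# starting the whitespace-separated position table (cits_position, residue,
# role).


def load_reference(path: str | Path) -> ReferenceDomain:
    name = None
    offset = None
    seq_parts: list[str] = []
    pocket: list[PocketPosition] = []
    section = "header"
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                section = "sequence"
                continue
            if line == "[positions]":
                section = "positions"
                continue
            if section == "header":
                if "=" not in line:
                    raise ParseError(f"expected 'key = value', got {line!r}", lineno)
                key, _, value = (s.strip() for s in line.partition("="))
                if key == "name":
                    name = value
                elif key == "numbering_offset":
                    offset = int(value)
                else:
                    raise ParseError(f"unknown header key {key!r}", lineno)
            elif section == "sequence":
                seq_parts.append(line)
            else:
                fields = line.split()
                if len(fields) != 3:
                    raise ParseError("expected 'position residue role'", lineno)
                pos_s, residue, role = fields
                if role not in (ROLE_POCKET, ROLE_DYAD):
                    raise ParseError(f"unknown role {role!r}", lineno)
                pocket.append(PocketPosition(int(pos_s), residue, role))
    if name is None or offset is None or not seq_parts:
        raise ParseError("reference file missing name, numbering_offset, or sequence")
    ref = ReferenceDomain(name, "".join(seq_parts), offset, pocket)
    _require_valid(ref)
    return ref


def write_reference(ref: ReferenceDomain, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"name = {ref.name}\n")
        fh.write(f"numbering_offset = {ref.numbering_offset}\n")
        fh.write(f">{ref.name}\n")
        for i in range(0, len(ref.sequence), 60):
            fh.write(ref.sequence[i : i + 60] + "\n")
        fh.write("[positions]\n")
        for p in ref.pocket:
            fh.write(f"{p.cits_position}\t{p.reference_residue}\t{p.role}\n")


def default_reference() -> ReferenceDomain:
    """The packaged CitS MT-domain reference annotation."""
    path = resources.files("mtminer.data") / "cits_mt_reference.txt"
    with resources.as_file(path) as p:
        return load_reference(p)


# ---------------------------------------------------------------------------
# Catalog TSV I/O
#
# Tab-separated, '#' comments, UTF-8; methylated_rounds encoded "2+3".

_CATALOG_COLUMNS = ["name", "product", "n_extensions", "methylated_rounds", "fingerprint", "group"]


def parse_rounds(text: str) -> frozenset[int]:
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(int(tok) for tok in text.split("+"))


def load_catalog(path: str | Path, ref: ReferenceDomain) -> list[KnownSynthase]:
    """Load a synthase catalog, validating every row against the reference."""
    n_pocket = len(ref.pocket)
    entries: list[KnownSynthase] = []
    with open(path, encoding="utf-8", newline="") as fh:
        lines = [(i, line) for i, line in enumerate(fh, 1) if line.strip() and not line.lstrip().startswith("#")]
    if not lines:
        raise ParseError("catalog file has no header row")
    header_line_no, header_raw = lines[0]
    header = header_raw.rstrip("\n").split("\t")
    if header != _CATALOG_COLUMNS:
        raise ParseError(
            f"expected header {_CATALOG_COLUMNS}, got {header}", header_line_no
        )
    for lineno, raw in lines[1:]:
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != len(_CATALOG_COLUMNS):
            raise ParseError(
                f"expected {len(_CATALOG_COLUMNS)} tab-separated fields, got {len(fields)}",
                lineno,
            )
        name, product, n_ext_s, rounds_s, fingerprint, group = fields
        try:
            pattern = MethylationPattern(int(n_ext_s), parse_rounds(rounds_s))
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"bad methylation pattern: {exc}", lineno) from exc
        if len(fingerprint) != n_pocket:
            raise ValidationError(
                f"line {lineno}: fingerprint {fingerprint!r} has length "
                f"{len(fingerprint)}, expected {n_pocket}"
            )
        bad = set(fingerprint) - set(AMINO_ACIDS + GAP)
        if bad:
            raise ValidationError(
                f"line {lineno}: fingerprint contains invalid characters {sorted(bad)}"
            )
        entries.append(KnownSynthase(name, product, pattern, fingerprint, group))
    return entries


def write_catalog(entries: Iterable[KnownSynthase], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CATALOG_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.name,
                    e.product_name,
                    e.pattern.n_extensions,
                    e.pattern.encode_rounds(),
                    e.fingerprint,
                    e.group_label,
                ]
            )


def default_catalog(ref: ReferenceDomain | None = None) -> list[KnownSynthase]:
    """The packaged catalog of characterized synthases."""
    if ref is None:
        ref = default_reference()
    path = resources.files("mtminer.data") / "catalog.tsv"
    with resources.as_file(path) as p:
        return load_catalog(p, ref)
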