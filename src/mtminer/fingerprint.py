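"""Reference-anchored fingerprinting of candidate MT domains.

A candidate MT domain is globally aligned to the CitS reference (Needleman-
Wunsch, BLOSUM62, affine gaps), CitS pocket coordinates are mapped through the
alignment, and the candidate residues at the 17 pocket positions are read out
as its fingerprint.  The same coordinate mapping renders point-mutation
proposals in the candidate's own numbering — e.g. replacing the residue at the
site corresponding to CitS Val2101 or Met2094.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .locate import check_protein
from .reference import GAP, AMINO_ACIDS, ReferenceDomain

#: Affine gap penalties for the global alignment: a gap of length k costs
#: OPEN + (k - 1) * EXTEND.
GAP_OPEN = 10.0
GAP_EXTEND = 1.0


@functools.lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


@dataclass
class PairwiseAlignment:
    """A global reference-candidate alignment with per-column coordinate maps."""

    aligned_ref: str
    aligned_cand: str
    score: float

    def __post_init__(self):
        if len(self.aligned_ref) != len(self.aligned_cand):
            raise ValidationError("gapped rows have different lengths")
        # column -> (1-based ref position | None, 1-based candidate position | None)
        self.columns: list[tuple[Optional[int], Optional[int]]] = []
        r = c = 0
        for ar, ac in zip(self.aligned_ref, self.aligned_cand):
            rp = cp = None
            if ar != GAP:
                r += 1
                rp = r
            if ac != GAP:
                c += 1
                cp = c
            self.columns.append((rp, cp))
        self._ref_to_cand = {rp: cp for rp, cp in self.columns if rp is not None}

    def candidate_position(self, ref_position: int) -> Optional[int]:
        """1-based candidate index aligned to a 1-based reference index, or None."""
        return self._ref_to_cand[ref_position]

    def degapped(self) -> tuple[str, str]:
        return self.aligned_ref.replace(GAP, ""), self.aligned_cand.replace(GAP, "")


@dataclass(frozen=True)
class Fingerprint:
    """17 candidate residues at the CitS pocket positions, in pocket order.

    ``cand_positions[i]`` is the 1-based candidate residue index behind
    ``residues[i]``, or None where the pocket position is deleted ('-').
    """

    residues: str
    source_name: str
    cand_positions: tuple[Optional[int], ...]

    def __post_init__(self):
        if len(self.residues) != len(self.cand_positions):
            raise ValidationError("residues and cand_positions lengths differ")
        non_gap = [p for p in self.cand_positions if p is not None]
        if any(a >= b for a, b in zip(non_gap, non_gap[1:])):
            raise ValidationError("cand_positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MutationProposal:
    """A point-mutation design rendered in candidate coordinates."""

    label: str
    candidate_position: int
    original: str
    target: str
    cits_position: int


def align_to_reference(candidate_mt: str, ref: ReferenceDomain) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment of a candidate MT domain to the reference.

    BLOSUM62 scoring with affine gaps (open 10, extend 1); Biopython's
    deterministic alignment enumeration makes the result reproducible.
    """
    if not candidate_mt or not ref.sequence:
        raise ValidationError("cannot align empty sequences")
    check_protein(candidate_mt)
    check_protein(ref.sequence)
    aln = _aligner().align(ref.sequence, candidate_mt)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def map_reference_position(
    aln: PairwiseAlignment, ref: ReferenceDomain, cits_pos: int
) -> Optional[int]:
    """Candidate residue index (1-based) aligned to a CitS position, or None for a gap."""
    idx = ref.index_of(cits_pos)  # raises if outside the reference range
    return aln.candidate_position(idx + 1)


def extract_fingerprint(
    candidate_mt: str, ref: ReferenceDomain, source_name: str = ""
) -> Fingerprint:
    """Align the candidate to the reference and read out the 17 pocket residues."""
    aln = align_to_reference(candidate_mt, ref)
    residues = []
    positions: list[Optional[int]] = []
    for p in ref.pocket:
        cand_pos = map_reference_position(aln, ref, p.cits_position)
        if cand_pos is None:
            residues.append(GAP)
            positions.append(None)
        else:
            residues.append(candidate_mt[cand_pos - 1])
            positions.append(cand_pos)
    return Fingerprint("".join(residues), source_name, tuple(positions))


def fingerprint_distance(a: Fingerprint | str, b: Fingerprint | str) -> int:
    """Hamming distance between fingerprints.

    A gap against a residue counts as one difference (a deleted pocket residue
    is functionally a difference); gap against gap counts zero.
    """
    sa = a.residues if isinstance(a, Fingerprint) else a
    sb = b.residues if isinstance(b, Fingerprint) else b
    if len(sa) != len(sb):
        raise ValidationError(f"fingerprint lengths differ: {len(sa)} vs {len(sb)}")
    return sum(
        1 for x, y in zip(sa, sb) if x != y and not (x == GAP and y == GAP)
    )


def propose_site_mutation(
    candidate_mt: str,
    ref: ReferenceDomain,
    cits_pos: int,
    target_aa: str,
) -> MutationProposal:
    """Design a point mutation at the candidate site corresponding to a CitS position.

    The label uses the candidate's own coordinates, e.g. aligning CitS 2101
    onto a candidate with Phe at its position 2044 and asking for Leu yields
    "F2044L".
    """
    if target_aa not in AMINO_ACIDS:
        raise ValidationError(f"target {target_aa!r} is not an amino acid")
    aln = align_to_reference(candidate_mt, ref)
    cand_pos = map_reference_position(aln, ref, cits_pos)
    if cand_pos is None:
        raise ValidationError(
            f"site corresponding to CitS {cits_pos} is deleted in the candidate"
        )
    original = candidate_mt[cand_pos - 1]
    if original == target_aa:
        raise ValidationError(
            f"candidate already carries {target_aa} at position {cand_pos}"
        )
    return MutationProposal(
        label=f"{original}{cand_pos}{target_aa}",
        candidate_position=cand_pos,
        original=original,
        target=target_aa,
        cits_position=cits_pos,
    )


def write_fingerprints_tsv(fingerprints: list[Fingerprint], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tfingerprint\tcand_positions\n")
        for fp in fingerprints:
            pos = ",".join("-" if p is None else str(p) for p in fp.cand_positions)
            fh.write(f"{fp.source_name}\t{fp.residues}\t{pos}\n")
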