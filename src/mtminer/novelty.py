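"""Novelty scoring of candidate fingerprints against the synthase catalog.

This is the decision procedure of the mining chain: a candidate whose pocket
residues are unseen at their slot in every characterized synthase — and above
all one whose residue falls in a different chemistry class, such as an acidic
glutamate where only nonpolar residues are known — is the kind of outlier
worth characterizing.  A methylation pattern is predicted by nearest-neighbor
transfer from the catalog, and candidates are ranked by a weighted count of
their novel and class-changing positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .errors import ValidationError
from .fingerprint import Fingerprint, fingerprint_distance
from .reference import (
    GAP,
    AMINO_ACIDS,
    KnownSynthase,
    MethylationPattern,
    ReferenceDomain,
)

#: Four-class chemistry partition of the amino acids.  His sits with the
#: basic residues despite its frequent catalytic roles; the table is a module
#: constant and can be monkey-patched for other conventions.
CHEMISTRY_CLASSES = {
    "nonpolar": frozenset("AVLIMFWPG"),
    "polar": frozenset("STNQYC"),
    "acidic": frozenset("DE"),
    "basic": frozenset("KRH"),
}

_CLASS_OF = {aa: label for label, members in CHEMISTRY_CLASSES.items() for aa in members}

DEFAULT_CLASS_WEIGHT = 2.0


def chemistry_class(aa: str) -> str:
    """Chemistry class label of a one-letter residue; '-' maps to "gap"."""
    if aa == GAP:
        return "gap"
    if aa not in AMINO_ACIDS:
        raise ValidationError(f"unknown residue symbol {aa!r}")
    return _CLASS_OF[aa]


@dataclass
class NoveltyReport:
    """Per-candidate novelty assessment against the catalog."""

    candidate: str
    fingerprint: str
    novel_positions: set[int]
    class_change_positions: set[int]
    min_distance: int
    nearest: list[str]
    predicted_pattern: Optional[MethylationPattern]
    ambiguous: bool
    score: float

    def __post_init__(self):
        if not self.class_change_positions <= self.novel_positions:
            raise ValidationError("class-change positions must be novel positions")
        if self.min_distance < 0 or self.score < 0:
            raise ValidationError("min_distance and score must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate,
            "fingerprint": self.fingerprint,
            "novel_positions": sorted(self.novel_positions),
            "class_change_positions": sorted(self.class_change_positions),
            "min_distance": self.min_distance,
            "nearest": list(self.nearest),
            "predicted_pattern": None
            if self.predicted_pattern is None
            else {
                "n_extensions": self.predicted_pattern.n_extensions,
                "methylated_rounds": sorted(self.predicted_pattern.methylated_rounds),
            },
            "ambiguous": self.ambiguous,
            "score": self.score,
        }


def _fingerprint_string(fp: Fingerprint | str) -> str:
    return fp.residues if isinstance(fp, Fingerprint) else fp


def _slot_labels(n_slots: int, ref: Optional[ReferenceDomain]) -> list[int]:
    if ref is None:
        return list(range(1, n_slots + 1))
    positions = ref.pocket_positions()
    if len(positions) != n_slots:
        raise ValidationError(
            f"reference has {len(positions)} pocket positions, fingerprint has {n_slots}"
        )
    return positions


def position_novelty(
    fp: Fingerprint | str,
    catalog: Sequence[KnownSynthase],
    ref: Optional[ReferenceDomain] = None,
) -> tuple[set[int], set[int]]:
    """Slots whose residue (or chemistry class) is unseen in the catalog.

    Returns ``(novel_positions, class_change_positions)`` labelled by CitS
    position when a reference is given, else by 1-based slot index.  A gap in
    the candidate is novel unless some catalog entry has a gap at that slot.
    """
    if not catalog:
        raise ValidationError("catalog is empty")
    s = _fingerprint_string(fp)
    labels = _slot_labels(len(s), ref)
    novel: set[int] = set()
    class_change: set[int] = set()
    for i, aa in enumerate(s):
        seen = {e.fingerprint[i] for e in catalog}
        if aa in seen:
            continue
        novel.add(labels[i])
        seen_classes = {chemistry_class(x) for x in seen}
        if chemistry_class(aa) not in seen_classes:
            class_change.add(labels[i])
    return novel, class_change


def novelty_score(
    fp: Fingerprint | str,
    catalog: Sequence[KnownSynthase],
    w_class: float = DEFAULT_CLASS_WEIGHT,
    ref: Optional[ReferenceDomain] = None,
) -> float:
    """``|novel| + w_class * |class_change|``; zero for any catalog member."""
    if w_class < 0:
        raise ValidationError("w_class must be nonnegative")
    novel, class_change = position_novelty(fp, catalog, ref)
    return len(novel) + w_class * len(class_change)


def predict_pattern(
    fp: Fingerprint | str, catalog: Sequence[KnownSynthase]
) -> tuple[Optional[MethylationPattern], list[str], int, bool]:
    """Nearest-neighbor methylation-pattern transfer.

    Returns ``(pattern, nearest_names, min_distance, ambiguous)``; when tied
    nearest entries disagree on the pattern, ``pattern`` is None and
    ``ambiguous`` is True with every tied entry listed.
    """
    if not catalog:
        raise ValidationError("catalog is empty")
    s = _fingerprint_string(fp)
    dists = [(fingerprint_distance(s, e.fingerprint), e) for e in catalog]
    min_d = min(d for d, _ in dists)
    tied = [e for d, e in dists if d == min_d]
    patterns = {e.pattern for e in tied}
    if len(patterns) == 1:
        return tied[0].pattern, [e.name for e in tied], min_d, False
    return None, [e.name for e in tied], min_d, True


def assess_candidate(
    name: str,
    fp: Fingerprint | str,
    catalog: Sequence[KnownSynthase],
    ref: Optional[ReferenceDomain] = None,
    w_class: float = DEFAULT_CLASS_WEIGHT,
) -> NoveltyReport:
    """Full novelty report for one candidate fingerprint."""
    novel, class_change = position_novelty(fp, catalog, ref)
    pattern, nearest, min_d, ambiguous = predict_pattern(fp, catalog)
    return NoveltyReport(
        candidate=name,
        fingerprint=_fingerprint_string(fp),
        novel_positions=novel,
        class_change_positions=class_change,
        min_distance=min_d,
        nearest=nearest,
        predicted_pattern=pattern,
        ambiguous=ambiguous,
        score=len(novel) + w_class * len(class_change),
    )


def rank_candidates(reports: Sequence[NoveltyReport]) -> list[NoveltyReport]:
    """Descending score; ties by descending min_distance, then name."""
    return sorted(
        reports, key=lambda r: (-r.score, -r.min_distance, r.candidate)
    )


def write_reports_json(reports: Sequence[NoveltyReport], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_ranked_tsv(reports: Sequence[NoveltyReport], path: str | Path) -> None:
    ranked = rank_candidates(reports)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "rank\tcandidate\tscore\tmin_distance\tnearest\tnovel_positions\t"
            "class_change_positions\tpredicted_pattern\n"
        )
        for rank, r in enumerate(ranked, 1):
            pattern = (
                "ambiguous"
                if r.ambiguous
                else f"{r.predicted_pattern.n_extensions}:{r.predicted_pattern.encode_rounds()}"
            )
            fh.write(
                f"{rank}\t{r.candidate}\t{r.score:g}\t{r.min_distance}\t"
                f"{','.join(r.nearest)}\t"
                f"{','.join(map(str, sorted(r.novel_positions)))}\t"
                f"{','.join(map(str, sorted(r.class_change_positions)))}\t"
                f"{pattern}\n"
            )
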