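"""Profile-based domain location in multidomain PKS proteins.

Each of the six NR-PKS domain families (SAT, KS, AT, PT, ACP, MT) is
represented by a position-specific scoring matrix (PSSM) built from a packaged
seed alignment.  Candidate proteins are scanned with a local
profile-to-sequence alignment (Gotoh affine-gap dynamic programming, scores in
bits), hits are reported best-first with already-assigned residues masked, and
MT envelopes are extended by 30 C-terminal residues before extraction — the
flanking stretch carries part of the substrate-binding pocket's context.

Profiles are deliberately simple log-odds PSSMs rather than full profile HMMs;
a profile-HMM backend could be swapped in behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .composition import AA_INDEX, BACKGROUND_VECTOR
from .errors import (
    AmbiguousArchitectureError,
    SequenceAlphabetError,
    ValidationError,
)
from .reference import AMINO_ACIDS, GAP

#: Supported domain families, in canonical NR-PKS order.
FAMILIES = ("SAT", "KS", "AT", "PT", "ACP", "MT")

#: Families that must all be present for the NR-PKS flag (SAT is optional).
_NRPKS_CORE = frozenset({"KS", "AT", "PT", "ACP"})

#: C-terminal extension applied to MT envelopes before extraction.
MT_EXTENSION = 30

#: Default reporting threshold for domain hits, in bits.  Chosen well above
#: the largest spurious local-alignment score observed on random background
#: sequences of realistic length, so that fixture-scale scans stay clean.
DEFAULT_THRESHOLD_BITS = 35.0

#: Affine gap penalties against profile columns, in bits.
GAP_OPEN_BITS = 8.0
GAP_EXTEND_BITS = 1.0

#: Floor for per-column log-odds scores (keeps PSSMs finite at zero pseudocount).
MIN_SCORE_BITS = -20.0

_NEG = -1.0e30


def check_protein(sequence: str) -> None:
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise SequenceAlphabetError(bad)


@dataclass
class SeedAlignment:
    """A gapped seed alignment for one domain family."""

    family: str
    rows: list[str]

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unsupported family {self.family!r}")
        if len(self.rows) < 2:
            raise ValidationError("seed alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValidationError(f"rows have differing lengths {sorted(lengths)}")
        ncol = lengths.pop()
        if ncol == 0 or not any(
            all(row[c] != GAP for row in self.rows) for c in range(ncol)
        ):
            raise ValidationError("seed alignment has no ungapped column")
        for row in self.rows:
            bad = set(row) - set(AMINO_ACIDS + GAP)
            if bad:
                raise SequenceAlphabetError(bad)


@dataclass
class DomainProfile:
    """Log-odds PSSM over match columns of a seed alignment (scores in bits)."""

    family: str
    scores: np.ndarray  # (length, 20)
    background: np.ndarray = field(default_factory=lambda: BACKGROUND_VECTOR.copy())

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class DomainHit:
    """A located domain: 1-based inclusive envelope plus the extraction endpoint."""

    family: str
    start: int
    end: int
    score: float
    extended_end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValidationError(f"bad envelope [{self.start}, {self.end}]")


def _hit(family: str, start: int, end: int, score: float, protein_length: int) -> DomainHit:
    ext = min(end + MT_EXTENSION, protein_length) if family == "MT" else end
    return DomainHit(family, start, end, score, ext)


# ---------------------------------------------------------------------------
# Profile construction


def build_profile(seed: SeedAlignment, pseudocount_weight: float = 1.0) -> DomainProfile:
    """PSSM from a seed alignment.

    Columns with more than 50% gap characters are treated as insert columns
    and dropped.  For a match column, ``score(c, a) =
    log2((f_ca + alpha * q_a) / ((1 + alpha) * q_a))`` where ``f_ca`` is the
    residue frequency among non-gap rows, ``q`` the background and ``alpha``
    the pseudocount weight.
    """
    seed.validate()
    if pseudocount_weight < 0:
        raise ValidationError("pseudocount_weight must be nonnegative")
    nrow = len(seed.rows)
    ncol = len(seed.rows[0])
    columns = []
    for c in range(ncol):
        col = [row[c] for row in seed.rows]
        n_gap = col.count(GAP)
        if n_gap / nrow > 0.5:
            continue  # insert column
        counts = np.zeros(20)
        for aa in col:
            if aa != GAP:
                counts[AA_INDEX[aa]] += 1
        freqs = counts / counts.sum()
        columns.append(freqs)
    if not columns:
        raise ValidationError("no match columns in seed alignment")
    f = np.array(columns)
    q = BACKGROUND_VECTOR
    alpha = pseudocount_weight
    with np.errstate(divide="ignore"):
        scores = np.log2((f + alpha * q) / ((1.0 + alpha) * q))
    # keep scores finite: residues unseen at zero pseudocount get a hard floor
    return DomainProfile(seed.family, np.maximum(scores, MIN_SCORE_BITS))


def consensus(seed: SeedAlignment) -> str:
    """Majority-rule consensus over match columns; ties break alphabetically."""
    seed.validate()
    nrow = len(seed.rows)
    out = []
    for c in range(len(seed.rows[0])):
        col = [row[c] for row in seed.rows if row[c] != GAP]
        if (nrow - len(col)) / nrow > 0.5:
            continue
        best = max(sorted(set(col)), key=col.count)
        out.append(best)
    return "".join(out)


def read_seed_alignment(path: str | Path, family: str) -> SeedAlignment:
    rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    seed = SeedAlignment(family, rows)
    seed.validate()
    return seed


def default_seed_alignments() -> dict[str, SeedAlignment]:
    """The packaged seed alignments, one per supported family."""
    seeds = {}
    base = resources.files("mtminer.data") / "seeds"
    for family in FAMILIES:
        with resources.as_file(base / f"{family}.afa") as p:
            seeds[family] = read_seed_alignment(p, family)
    return seeds


def default_profiles(pseudocount_weight: float = 1.0) -> dict[str, DomainProfile]:
    return {
        fam: build_profile(seed, pseudocount_weight)
        for fam, seed in default_seed_alignments().items()
    }


# ---------------------------------------------------------------------------
# Local profile-sequence alignment (Gotoh, vectorized over profile columns)


def _dp_matrices(seq_scores: np.ndarray):
    """Fill local-alignment DP matrices.

    ``seq_scores``: (n, L) match score of protein residue i against profile
    column j.  Returns (M, Ix, Iy) of shape (n+1, L+1).  State M consumes a
    residue and a column; Ix a residue only (gap in the profile); Iy a column
    only (gap in the sequence).
    """
    n, L = seq_scores.shape
    go, ge = GAP_OPEN_BITS, GAP_EXTEND_BITS
    M = np.full((n + 1, L + 1), _NEG)
    Ix = np.full((n + 1, L + 1), _NEG)
    Iy = np.full((n + 1, L + 1), _NEG)
    j_arr = np.arange(L + 1) * ge
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        prev_best = np.maximum(prev_best, 0.0)
        M[i, 1:] = seq_scores[i - 1] + prev_best[:-1]
        Ix[i] = np.maximum(M[i - 1] - go, Ix[i - 1] - ge)
        # Iy[i, j] = max(M[i, j-1] - go, Iy[i, j-1] - ge), solved by a
        # running maximum of M[i, j] + ge*j.
        b = M[i] + j_arr
        c = np.empty(L + 1)
        c[0] = _NEG
        c[1:] = b[:-1] - go + ge
        np.maximum.accumulate(c, out=c)
        Iy[i] = c - j_arr
    return M, Ix, Iy


def _traceback_start(M, Ix, Iy, seq_scores, i, j) -> int:
    """Walk back from the best M cell; return the first protein residue (1-based)."""
    go, ge = GAP_OPEN_BITS, GAP_EXTEND_BITS
    state = "M"
    tol = 1e-6
    while True:
        if state == "M":
            target = M[i, j] - seq_scores[i - 1, j - 1]
            if abs(M[i - 1, j - 1] - target) < tol:
                i, j = i - 1, j - 1
            elif abs(Ix[i - 1, j - 1] - target) < tol:
                i, j, state = i - 1, j - 1, "Ix"
            elif abs(Iy[i - 1, j - 1] - target) < tol:
                i, j, state = i - 1, j - 1, "Iy"
            else:  # local start
                return i
        elif state == "Ix":
            if abs(M[i - 1, j] - go - Ix[i, j]) < tol:
                i, state = i - 1, "M"
            else:
                i = i - 1
        else:  # Iy
            if abs(M[i, j - 1] - go - Iy[i, j]) < tol:
                j, state = j - 1, "M"
            else:
                j = j - 1


def scan_protein(
    protein: str,
    profile: DomainProfile,
    threshold_bits: float = DEFAULT_THRESHOLD_BITS,
) -> list[DomainHit]:
    """Locate non-overlapping occurrences of a domain profile in a protein.

    Hits are found best-first: after each hit its residues are masked and the
    scan repeats until the best remaining score falls below the threshold.
    """
    if not protein:
        raise ValidationError("empty protein sequence")
    check_protein(protein)
    n = len(protein)
    idx = np.fromiter((AA_INDEX[aa] for aa in protein), dtype=np.intp, count=n)
    base_scores = profile.scores[:, idx].T.copy()  # (n, L)
    masked = np.zeros(n, dtype=bool)
    hits: list[DomainHit] = []
    while True:
        seq_scores = base_scores.copy()
        seq_scores[masked, :] = _NEG
        M, Ix, Iy = _dp_matrices(seq_scores)
        best_flat = int(np.argmax(M))
        i, j = divmod(best_flat, M.shape[1])
        score = float(M[i, j])
        if score < threshold_bits:
            break
        start = _traceback_start(M, Ix, Iy, seq_scores, i, j)
        hits.append(_hit(profile.family, start, i, score, n))
        masked[start - 1 : i] = True
        if masked.all():
            break
    return hits


def scan_all(
    protein: str,
    profiles: dict[str, DomainProfile],
    threshold_bits: float = DEFAULT_THRESHOLD_BITS,
) -> list[DomainHit]:
    """Scan one protein with every profile; concatenated hits sorted by start."""
    hits: list[DomainHit] = []
    for family in FAMILIES:
        if family in profiles:
            hits.extend(scan_protein(protein, profiles[family], threshold_bits))
    return sorted(hits, key=lambda h: (h.start, h.family))


# ---------------------------------------------------------------------------
# Extraction and architecture


def extract_mt_domain(protein: str, hit: DomainHit) -> str:
    """Envelope plus the 30-residue C-terminal extension, clipped at the sequence end."""
    if hit.family != "MT":
        raise ValidationError(f"extract_mt_domain requires an MT hit, got {hit.family}")
    if hit.end > len(protein):
        raise ValidationError("hit envelope exceeds protein length")
    return protein[hit.start - 1 : min(hit.end + MT_EXTENSION, len(protein))]


def classify_architecture(hits: list[DomainHit]) -> tuple[str, bool]:
    """Domain string in N-to-C order plus the NR-PKS flag.

    The flag is true when KS, AT, PT and ACP are all present (SAT optional);
    reducing domains are outside this locator's model, so their absence is
    implied.  Overlapping hits of different families make the architecture
    ambiguous and raise.
    """
    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end and a.family != b.family:
            raise AmbiguousArchitectureError(
                f"{a.family} [{a.start},{a.end}] overlaps {b.family} [{b.start},{b.end}]"
            )
    arch = "-".join(h.family for h in ordered)
    families = {h.family for h in ordered}
    return arch, _NRPKS_CORE <= families


def write_hits_tsv(hits_by_protein: dict[str, list[DomainHit]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tfamily\tstart\tend\tscore\textended_end\n")
        for name, hits in hits_by_protein.items():
            for h in hits:
                fh.write(
                    f"{name}\t{h.family}\t{h.start}\t{h.end}\t{h.score:.2f}\t{h.extended_end}\n"
                )
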