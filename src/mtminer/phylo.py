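"""Reference-anchored alignment, distance phylogenetics, and sequence logos.

The multiple alignment is a star alignment: every member is pairwise-aligned
to the CitS reference and the pairwise alignments are merged on reference
columns, member insertions being padded with gaps in all other rows.  Observed
mismatch proportions are corrected for multiple substitutions with the
20-state (protein) Jukes-Cantor model, trees are built with Saitou-Nei
Neighbor-Joining, and tree similarity is quantified with the Robinson-Foulds
bipartition distance.  Per-group conservation is summarized as sequence-logo
matrices: per-column residue frequencies plus information content in bits,
optionally with the small-sample entropy correction.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from skbio import TreeNode

from .composition import AA_INDEX
from .errors import ValidationError
from .fingerprint import align_to_reference
from .reference import GAP, AMINO_ACIDS, ReferenceDomain

#: Number of amino-acid states in the protein Jukes-Cantor generalization.
JC_STATES = 20

#: Corrected distance assigned when p reaches the JC saturation point.
DEFAULT_JC_CAP = 10.0

LOG2_20 = math.log2(20)


# ---------------------------------------------------------------------------
# Star multiple alignment


@dataclass
class StarMSA:
    """Reference-anchored multiple alignment; row 0 is the reference."""

    names: list[str]
    rows: list[str]
    reference_index: int = 0

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("MSA rows have differing lengths")
        if len(self.names) != len(self.rows):
            raise ValidationError("names and rows differ in number")

    def degap(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def star_msa(members: Sequence[tuple[str, str]], ref: ReferenceDomain) -> StarMSA:
    """Merge pairwise reference alignments of all members into one MSA.

    Insertions relative to the reference are anchored after the reference
    position they follow and left-justified within the widest insertion block
    at that anchor.
    """
    if len(members) < 2:
        raise ValidationError("star MSA needs at least 2 member sequences")
    R = len(ref.sequence)
    per_member = []
    ins_len = [0] * (R + 1)  # widest insertion after ref position r (0 = before start)
    for name, seq in members:
        aln = align_to_reference(seq, ref)
        chars: dict[int, str] = {}
        inserts: dict[int, str] = {}
        anchor = 0
        for (rp, cp), ac in zip(aln.columns, aln.aligned_cand):
            if rp is None:
                inserts[anchor] = inserts.get(anchor, "") + ac
            else:
                anchor = rp
                chars[rp] = ac
        per_member.append((name, chars, inserts))
        for a, s in inserts.items():
            ins_len[a] = max(ins_len[a], len(s))

    def assemble(char_at, inserts) -> str:
        parts = [inserts.get(0, "").ljust(ins_len[0], GAP)]
        for r in range(1, R + 1):
            parts.append(char_at(r))
            parts.append(inserts.get(r, "").ljust(ins_len[r], GAP))
        return "".join(parts)

    names = [ref.name]
    rows = [assemble(lambda r: ref.sequence[r - 1], {})]
    for name, chars, inserts in per_member:
        names.append(name)
        rows.append(assemble(lambda r: chars.get(r, GAP), inserts))
    return StarMSA(names, rows)


# ---------------------------------------------------------------------------
# Distances


def p_distance(msa: StarMSA, i: int, j: int) -> float:
    """Fraction of differing residues over mutually non-gap columns."""
    a, b = msa.rows[i], msa.rows[j]
    shared = diff = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            shared += 1
            if x != y:
                diff += 1
    if shared == 0:
        raise ValidationError(f"rows {i} and {j} share no aligned columns")
    return diff / shared


def jc_distance(p: float, cap: float = DEFAULT_JC_CAP) -> float:
    """Protein Jukes-Cantor correction of an observed mismatch proportion.

    ``d = -(19/20) * ln(1 - (20/19) * p)``; at or beyond the saturation point
    p >= 19/20 the distance is set to ``cap``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p-distance {p} outside [0, 1]")
    b = (JC_STATES - 1) / JC_STATES
    if p >= b:
        return cap
    return -b * math.log(1.0 - p / b)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with named taxa."""

    names: list[str]
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.names)
        if self.data.shape != (n, n):
            raise ValidationError("matrix shape does not match names")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(self.data < 0):
            raise ValidationError("negative distances")


def msa_distance_matrix(
    msa: StarMSA, include_reference: bool = True, cap: float = DEFAULT_JC_CAP
) -> DistanceMatrix:
    """Jukes-Cantor-corrected pairwise distances between MSA rows."""
    idx = list(range(msa.n_rows))
    if not include_reference:
        idx = [i for i in idx if i != msa.reference_index]
    n = len(idx)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = jc_distance(p_distance(msa, idx[a], idx[b]), cap)
            D[a, b] = D[b, a] = d
    return DistanceMatrix([msa.names[i] for i in idx], D)


# ---------------------------------------------------------------------------
# Neighbor-Joining


@dataclass
class PhyloTree:
    """An unrooted tree (trifurcating root node) with named leaves."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return sorted(t.name for t in self.root.tips())

    def write_newick(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        self.root.write(buf, format="newick")
        text = buf.getvalue().strip()
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def read_newick(cls, source: str | Path) -> "PhyloTree":
        if isinstance(source, Path) or not str(source).lstrip().startswith("("):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        root = TreeNode.read(io.StringIO(text), format="newick")
        return cls(root)

    def leaf_path_length(self, a: str, b: str) -> float:
        return float(self.root.find(a).distance(self.root.find(b)))


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei Neighbor-Joining with deterministic tie-breaking.

    Ties on the Q criterion are broken by the lexicographically smallest pair
    of node labels (a node is labelled by the smallest leaf name beneath it);
    negative branch lengths are clamped to zero.
    """
    names = list(D.names)
    n = len(names)
    if n < 2:
        raise ValidationError("NJ needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]
    labels = list(names)
    d = D.data.astype(float).copy()

    def attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        child.length = max(0.0, float(length))
        parent.append(child)

    if n == 2:
        root = TreeNode()
        attach(root, nodes[0], d[0, 1] / 2.0)
        attach(root, nodes[1], d[0, 1] / 2.0)
        return PhyloTree(root)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best: tuple[float, tuple[str, str], int, int] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        attach(parent, nodes[i], li)
        attach(parent, nodes[j], lj)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((m - 1, m - 1))
        d_next[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d_next[-1, : m - 2] = d_next[: m - 2, -1] = new_d[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    root = TreeNode()
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    attach(root, nodes[0], (d01 + d02 - d12) / 2.0)
    attach(root, nodes[1], (d01 + d12 - d02) / 2.0)
    attach(root, nodes[2], (d02 + d12 - d01) / 2.0)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Robinson-Foulds


def _bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    leaves = set(tree.leaf_names)
    anchor = min(leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue  # trivial split
        if anchor in side:
            side = frozenset(leaves - side)
        parts.add(side)
    return parts


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise ValidationError("trees have different leaf sets")
    return len(_bipartitions(t1) ^ _bipartitions(t2))


# ---------------------------------------------------------------------------
# Sequence logos


@dataclass
class LogoMatrix:
    """Per-column residue frequencies, information content (bits) and sample sizes."""

    frequencies: np.ndarray  # (L, 20), rows sum to 1 over non-gap columns
    information: np.ndarray  # (L,)
    sample_sizes: np.ndarray  # (L,) non-gap counts

    @property
    def n_columns(self) -> int:
        return len(self.information)


def build_logo(
    strings: Sequence[str], correct_small_sample: bool = False
) -> LogoMatrix:
    """Logo matrix from equal-length residue strings (fingerprints or MSA columns).

    Information content is ``log2(20) - H_i - e_n`` with column entropy
    ``H_i`` over non-gap residues and small-sample correction
    ``e_n = 19 / (2 ln 2 n)`` when requested; values are clamped to
    ``[0, log2 20]``.
    """
    seqs = [s.residues if hasattr(s, "residues") else s for s in strings]
    if not seqs:
        raise ValidationError("cannot build a logo from no sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValidationError("logo input strings have differing lengths")
    L = len(seqs[0])
    freqs = np.zeros((L, 20))
    info = np.zeros(L)
    sizes = np.zeros(L, dtype=int)
    for c in range(L):
        col = [s[c] for s in seqs if s[c] != GAP]
        bad = set(col) - set(AMINO_ACIDS)
        if bad:
            raise ValidationError(f"column {c}: invalid residues {sorted(bad)}")
        sizes[c] = len(col)
        if not col:
            continue
        counts = np.zeros(20)
        for aa in col:
            counts[AA_INDEX[aa]] += 1
        f = counts / counts.sum()
        freqs[c] = f
        nz = f[f > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        e_n = (JC_STATES - 1) / (2.0 * math.log(2) * len(col)) if correct_small_sample else 0.0
        info[c] = min(max(LOG2_20 - entropy - e_n, 0.0), LOG2_20)
    return LogoMatrix(freqs, info, sizes)


def write_logo_tsv(logo: LogoMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("position\t" + "\t".join(AMINO_ACIDS) + "\tinformation\tn\n")
        for c in range(logo.n_columns):
            freqs = "\t".join(f"{v:.6f}" for v in logo.frequencies[c])
            fh.write(f"{c + 1}\t{freqs}\t{logo.information[c]:.6f}\t{logo.sample_sizes[c]}\n")


def write_msa_fasta(msa: StarMSA, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n{row}\n")
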