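"""Deterministic synthetic fixtures: PKS proteins, MT variants, catalogs, trees.

Every generator is a pure function of its parameters and an integer seed.
Proteins are assembled from family seed-alignment consensus blocks joined by
random background linkers; MT blocks are copies of the CitS reference with
the 17 pocket positions overwritten by a prescribed fingerprint and the
remaining sites mutated at a given rate.  Divergence in synthetic catalogs is
i.i.d. per-slot perturbation, not evolution along a tree — adequate ground
truth for recovery tests, not a simulation of real sequence families.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .composition import BACKGROUND_VECTOR
from .errors import ValidationError
from .locate import FAMILIES, consensus, default_seed_alignments
from .phylo import DistanceMatrix, PhyloTree
from .reference import (
    GAP,
    AMINO_ACIDS,
    KnownSynthase,
    MethylationPattern,
    ReferenceDomain,
    write_catalog,
)

_AA = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth for one generated protein."""

    name: str
    domains: tuple[tuple[str, int, int], ...]  # (family, start, end), 1-based inclusive
    fingerprint: str
    seed: int
    mutation_rate: float

    def __post_init__(self):
        spans = sorted((s, e) for _, s, e in self.domains)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError("planted domain intervals overlap")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "domains": [list(d) for d in self.domains],
            "fingerprint": self.fingerprint,
            "seed": self.seed,
            "mutation_rate": self.mutation_rate,
        }


def generate_background(length: int, seed: int) -> str:
    """i.i.d. draws from the background amino-acid composition."""
    if length < 0:
        raise ValidationError("length must be nonnegative")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_AA, size=length, p=BACKGROUND_VECTOR))


def _mutate(seq: list[str], positions: Sequence[int], rate: float, rng) -> None:
    """Substitute each listed position with probability `rate` (to a different residue)."""
    for i in positions:
        if rng.random() < rate:
            choices = [aa for aa in AMINO_ACIDS if aa != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]


def _mutate_within_class(fp: list[str], rate: float, rng) -> None:
    """Chemistry-class-conservative substitutions (gaps left untouched)."""
    from .novelty import CHEMISTRY_CLASSES

    for i, aa in enumerate(fp):
        if aa == GAP or rng.random() >= rate:
            continue
        cls = next(members for members in CHEMISTRY_CLASSES.values() if aa in members)
        choices = sorted(cls - {aa})
        if choices:
            fp[i] = choices[rng.integers(len(choices))]


def synth_mt_variant(
    ref: ReferenceDomain,
    prescribed: str,
    substitution_rate: float,
    seed: int,
) -> tuple[str, FixtureTruth]:
    """Reference copy with pocket slots overwritten and non-pocket sites mutated.

    A ``'-'`` in the prescription deletes the pocket residue.  The
    substitution rate applies only to non-pocket sites, so the planted
    fingerprint is exact ground truth.
    """
    if len(prescribed) != len(ref.pocket):
        raise ValidationError(
            f"prescription length {len(prescribed)} != pocket size {len(ref.pocket)}"
        )
    if not 0.0 <= substitution_rate <= 0.3:
        raise ValidationError("substitution_rate must be within [0, 0.3]")
    bad = set(prescribed) - set(AMINO_ACIDS + GAP)
    if bad:
        raise ValidationError(f"invalid prescription characters {sorted(bad)}")
    rng = np.random.default_rng(seed)
    seq = list(ref.sequence)
    pocket_idx = [ref.index_of(p.cits_position) for p in ref.pocket]
    deletions = []
    for idx, aa in zip(pocket_idx, prescribed):
        if aa == GAP:
            deletions.append(idx)
        else:
            seq[idx] = aa
    non_pocket = [i for i in range(len(seq)) if i not in set(pocket_idx)]
    _mutate(seq, non_pocket, substitution_rate, rng)
    for idx in sorted(deletions, reverse=True):
        del seq[idx]
    truth = FixtureTruth(
        name=ref.name + "_variant",
        domains=(("MT", 1, len(seq)),),
        fingerprint=prescribed,
        seed=seed,
        mutation_rate=substitution_rate,
    )
    return "".join(seq), truth


@functools.lru_cache(maxsize=1)
def _family_consensus() -> dict[str, str]:
    return {fam: consensus(seed) for fam, seed in default_seed_alignments().items()}


def synth_pks(
    architecture: Sequence[str],
    mt_prescription: str,
    seed: int,
    substitution_rate: float = 0.05,
    name: str = "synthetic_pks",
) -> tuple[str, FixtureTruth]:
    """Multidomain protein: consensus blocks joined by background linkers (20-60 aa)."""
    if not architecture:
        raise ValidationError("architecture must name at least one family")
    unsupported = set(architecture) - set(FAMILIES)
    if unsupported:
        raise ValidationError(f"unsupported families {sorted(unsupported)}")
    rng = np.random.default_rng(seed)
    cons = _family_consensus()
    parts: list[str] = []
    domains: list[tuple[str, int, int]] = []
    pos = 0

    def linker() -> str:
        n = int(rng.integers(20, 61))
        block = "".join(np.random.default_rng(rng.integers(2**31)).choice(
            _AA, size=n, p=BACKGROUND_VECTOR))
        return block

    lead = linker()
    parts.append(lead)
    pos += len(lead)
    for k, family in enumerate(architecture):
        if family == "MT":
            block, _ = synth_mt_variant(
                _reference(), mt_prescription, substitution_rate, int(rng.integers(2**31))
            )
        else:
            block_list = list(cons[family])
            _mutate(block_list, range(len(block_list)), substitution_rate, rng)
            block = "".join(block_list)
        domains.append((family, pos + 1, pos + len(block)))
        parts.append(block)
        pos += len(block)
        tail = linker()
        parts.append(tail)
        pos += len(tail)
    truth = FixtureTruth(
        name=name,
        domains=tuple(domains),
        fingerprint=mt_prescription if "MT" in architecture else "",
        seed=seed,
        mutation_rate=substitution_rate,
    )
    return "".join(parts), truth


@functools.lru_cache(maxsize=1)
def _reference() -> ReferenceDomain:
    from .reference import default_reference

    return default_reference()


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic catalog group: label, pattern, member count, group fingerprint."""

    label: str
    pattern: MethylationPattern
    count: int
    fingerprint: str

    def __post_init__(self):
        if self.count < 1:
            raise ValidationError("group member count must be >= 1")


def synth_catalog(
    groups: Sequence[GroupSpec],
    divergence: float,
    seed: int,
    ref: ReferenceDomain | None = None,
    sequence_rate: float = 0.05,
) -> tuple[list[KnownSynthase], dict[str, str]]:
    """Synthetic catalog plus matching MT-domain sequences.

    Each member's fingerprint is its group fingerprint with every slot
    independently perturbed with probability ``divergence``.  Perturbations
    are chemistry-class-conservative (e.g. Met -> Leu, never Met -> Glu):
    within a group the pocket chemistry is preserved, mirroring the premise
    that the pocket residues of synthases sharing a methylation program vary
    only conservatively.  Member sequences are MT variants planted with the
    member fingerprint.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValidationError("divergence must be within [0, 1]")
    if ref is None:
        ref = _reference()
    rng = np.random.default_rng(seed)
    entries: list[KnownSynthase] = []
    sequences: dict[str, str] = {}
    for g in groups:
        if len(g.fingerprint) != len(ref.pocket):
            raise ValidationError(
                f"group {g.label}: fingerprint length {len(g.fingerprint)}"
            )
        for m in range(1, g.count + 1):
            fp = list(g.fingerprint)
            _mutate_within_class(fp, divergence, rng)
            name = f"{g.label}_m{m}"
            entries.append(
                KnownSynthase(name, g.label, g.pattern, "".join(fp), g.label)
            )
            seq, _ = synth_mt_variant(ref, "".join(fp), sequence_rate, int(rng.integers(2**31)))
            sequences[name] = seq
    return entries, sequences


# ---------------------------------------------------------------------------
# Random additive trees (ground truth for Neighbor-Joining recovery)


def random_additive_tree(n_leaves: int, seed: int) -> tuple[DistanceMatrix, PhyloTree]:
    """A random binary tree with uniform(0.1, 1.0) branch lengths and its
    exact additive leaf-to-leaf distance matrix."""
    if n_leaves < 3:
        raise ValidationError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    names = [f"T{i + 1}" for i in range(n_leaves)]

    def build(members: list[str]) -> TreeNode:
        if len(members) == 1:
            node = TreeNode(name=members[0])
        else:
            k = int(rng.integers(1, len(members)))
            node = TreeNode()
            for part in (members[:k], members[k:]):
                child = build(part)
                child.length = float(rng.uniform(0.1, 1.0))
                node.append(child)
        return node

    order = [names[i] for i in rng.permutation(n_leaves)]
    root = build(order)
    dm = root.tip_tip_distances()
    ids = list(dm.ids)
    return DistanceMatrix(ids, np.asarray(dm.data)), PhyloTree(root)


# ---------------------------------------------------------------------------
# Fixture bundle emission (FASTA + truth JSON + catalog TSV)


def write_fixture_bundle(
    out_dir: str | Path,
    seed: int,
    n_proteins: int = 3,
    substitution_rate: float = 0.05,
) -> dict[str, Path]:
    """Emit a self-contained demo fixture set for the CLI and examples."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = _reference()
    base_fp = "".join(p.reference_residue for p in ref.pocket)
    rng = np.random.default_rng(seed)
    fasta = out / "proteins.fasta"
    truth_path = out / "truth.json"
    catalog_path = out / "catalog.tsv"
    truths = []
    with open(fasta, "w", encoding="utf-8") as fh:
        for i in range(n_proteins):
            fp = list(base_fp)
            _mutate(fp, range(len(fp)), 0.1, rng)
            seq, truth = synth_pks(
                ["SAT", "KS", "AT", "PT", "ACP", "MT"],
                "".join(fp),
                int(rng.integers(2**31)),
                substitution_rate,
                name=f"synthetic_pks_{i + 1}",
            )
            fh.write(f">{truth.name}\n{seq}\n")
            truths.append(truth.to_dict())
    truth_path.write_text(json.dumps(truths, indent=2) + "\n", encoding="utf-8")
    groups = [
        GroupSpec("grpA", MethylationPattern(3, frozenset({1})), 3, base_fp),
        GroupSpec(
            "grpB",
            MethylationPattern(3, frozenset({1, 2})),
            3,
            base_fp[:12] + "F" + base_fp[13:],
        ),
    ]
    entries, _ = synth_catalog(groups, 0.05, int(rng.integers(2**31)), ref)
    write_catalog(entries, catalog_path)
    return {"fasta": fasta, "truth": truth_path, "catalog": catalog_path}
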