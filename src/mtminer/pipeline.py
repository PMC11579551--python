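"""End-to-end mining pipeline: FASTA in, ranked novelty report out.

For each input protein: locate domains, classify the architecture, extract
the MT domain (envelope + 30 residues), read out the CitS-anchored
fingerprint, and assess it against the catalog.  Globally: a Neighbor-Joining
tree of the extracted MT domains, optionally a KS-domain tree with the
Robinson-Foulds distance between the two (the co-evolution check), and
per-group catalog logos.  Everything is deterministic given the config.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .errors import AmbiguousArchitectureError, NoMTDomainError, ParseError
from .fingerprint import Fingerprint, extract_fingerprint, write_fingerprints_tsv
from .locate import (
    DEFAULT_THRESHOLD_BITS,
    DomainHit,
    classify_architecture,
    default_profiles,
    extract_mt_domain,
    read_seed_alignment,
    build_profile,
    scan_protein,
    write_hits_tsv,
    FAMILIES,
)
from .novelty import (
    DEFAULT_CLASS_WEIGHT,
    NoveltyReport,
    assess_candidate,
    rank_candidates,
    write_ranked_tsv,
)
from .phylo import (
    DEFAULT_JC_CAP,
    LogoMatrix,
    PhyloTree,
    build_logo,
    msa_distance_matrix,
    nj_tree,
    robinson_foulds,
    star_msa,
    write_logo_tsv,
)
from .reference import (
    KnownSynthase,
    ReferenceDomain,
    default_catalog,
    default_reference,
    load_catalog,
    load_reference,
)

SCHEMA_VERSION = "1.0"

log = logging.getLogger("mtminer")


@dataclass
class MiningConfig:
    """All knobs of the mining pipeline; paths default to the packaged data."""

    reference_path: Optional[str] = None
    catalog_path: Optional[str] = None
    seeds_dir: Optional[str] = None
    scan_threshold: float = DEFAULT_THRESHOLD_BITS
    jc_cap: float = DEFAULT_JC_CAP
    w_class: float = DEFAULT_CLASS_WEIGHT
    logo_small_sample: bool = False
    ks_tree: bool = False
    seed: int = 0

    def validate(self) -> None:
        for attr in ("reference_path", "catalog_path", "seeds_dir"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ParseError(f"{attr} does not exist: {p}")
        if self.scan_threshold < 0 or self.jc_cap <= 0 or self.w_class < 0:
            raise ParseError("numeric parameters out of range")


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def load_config(path: str | Path) -> MiningConfig:
    """Parse a simple ``key = value`` config file mirroring the CLI flags."""
    cfg = MiningConfig()
    types = MiningConfig.__dataclass_fields__
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"expected 'key = value', got {line!r}", lineno)
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in types:
                raise ParseError(f"unknown config key {key!r}", lineno)
            kind = types[key].type
            if kind == "float":
                setattr(cfg, key, float(value))
            elif kind == "int":
                setattr(cfg, key, int(value))
            elif kind == "bool":
                if value.lower() not in _BOOL:
                    raise ParseError(f"bad boolean {value!r}", lineno)
                setattr(cfg, key, _BOOL[value.lower()])
            else:
                setattr(cfg, key, value)
    return cfg


@dataclass
class CandidateResult:
    """Per-protein outcome of the mining chain."""

    name: str
    architecture: Optional[str]
    is_nrpks: bool
    hits: list[DomainHit]
    mt_fingerprint: Optional[Fingerprint]
    report: Optional[NoveltyReport]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "architecture": self.architecture,
            "is_nrpks": self.is_nrpks,
            "hits": [
                {
                    "family": h.family,
                    "start": h.start,
                    "end": h.end,
                    "score": round(h.score, 4),
                    "extended_end": h.extended_end,
                }
                for h in self.hits
            ],
            "mt_fingerprint": None
            if self.mt_fingerprint is None
            else self.mt_fingerprint.residues,
            "report": None if self.report is None else self.report.to_dict(),
        }


@dataclass
class MiningResult:
    candidates: list[CandidateResult]
    ranked: list[NoveltyReport]
    mt_tree: Optional[str]  # Newick
    ks_tree: Optional[str]
    rf_distance: Optional[int]
    logos: dict[str, LogoMatrix]
    config: MiningConfig

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "config": asdict(self.config),
            "candidates": [c.to_dict() for c in self.candidates],
            "ranking": [r.candidate for r in self.ranked],
            "mt_tree": self.mt_tree,
            "ks_tree": self.ks_tree,
            "rf_distance": self.rf_distance,
            "logo_groups": sorted(self.logos),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParseError(f"no sequences in {path}")
    return records


def _load_inputs(config: MiningConfig):
    ref = (
        default_reference()
        if config.reference_path is None
        else load_reference(config.reference_path)
    )
    catalog = (
        default_catalog(ref)
        if config.catalog_path is None
        else load_catalog(config.catalog_path, ref)
    )
    if config.seeds_dir is None:
        profiles = default_profiles()
    else:
        profiles = {}
        for family in FAMILIES:
            p = Path(config.seeds_dir) / f"{family}.afa"
            if p.exists():
                profiles[family] = build_profile(read_seed_alignment(p, family))
    return ref, catalog, profiles


def _domain_tree(
    domains: list[tuple[str, str]], anchor: ReferenceDomain, cap: float
) -> Optional[str]:
    """NJ tree over named domain sequences, anchored on `anchor`; None if < 3 leaves."""
    if len(domains) < 3:
        return None
    msa = star_msa(domains, anchor)
    D = msa_distance_matrix(msa, include_reference=False, cap=cap)
    return nj_tree(D).write_newick()


def mine(
    sequences: Sequence[tuple[str, str]] | str | Path,
    config: MiningConfig | None = None,
) -> MiningResult:
    """Run the full mining chain over protein sequences (FASTA path or pairs)."""
    config = config or MiningConfig()
    config.validate()
    if isinstance(sequences, (str, Path)):
        sequences = read_fasta(sequences)
    if not sequences:
        raise ParseError("no input sequences")
    ref, catalog, profiles = _load_inputs(config)
    log.info(
        "mine: %d sequences, scan_threshold=%.1f bits, jc_cap=%.1f, "
        "w_class=%.1f, seed=%d",
        len(sequences), config.scan_threshold, config.jc_cap,
        config.w_class, config.seed,
    )

    candidates: list[CandidateResult] = []
    mt_domains: list[tuple[str, str]] = []
    ks_domains: list[tuple[str, str]] = []
    for name, seq in sequences:
        hits: list[DomainHit] = []
        for family in FAMILIES:
            if family in profiles:
                hits.extend(scan_protein(seq, profiles[family], config.scan_threshold))
        hits.sort(key=lambda h: (h.start, h.family))
        try:
            architecture, is_nrpks = classify_architecture(hits)
        except AmbiguousArchitectureError as exc:
            log.warning("%s: ambiguous architecture (%s)", name, exc)
            architecture, is_nrpks = None, False
        mt_hits = [h for h in hits if h.family == "MT"]
        fingerprint = report = None
        if mt_hits:
            best_mt = max(mt_hits, key=lambda h: h.score)
            domain = extract_mt_domain(seq, best_mt)
            mt_domains.append((name, domain))
            fingerprint = extract_fingerprint(domain, ref, source_name=name)
            report = assess_candidate(name, fingerprint, catalog, ref, config.w_class)
        ks_hits = [h for h in hits if h.family == "KS"]
        if ks_hits:
            best_ks = max(ks_hits, key=lambda h: h.score)
            ks_domains.append((name, seq[best_ks.start - 1 : best_ks.end]))
        candidates.append(
            CandidateResult(name, architecture, is_nrpks, hits, fingerprint, report)
        )

    if not mt_domains:
        raise NoMTDomainError("no MT domain found in any input protein")

    mt_tree = _domain_tree(mt_domains, ref, config.jc_cap)
    ks_tree = rf = None
    if config.ks_tree and len(ks_domains) >= 3:
        anchor_name, anchor_seq = max(ks_domains, key=lambda d: len(d[1]))
        ks_anchor = ReferenceDomain(anchor_name + "_anchor", anchor_seq, 1, [])
        ks_tree = _domain_tree(ks_domains, ks_anchor, config.jc_cap)
        if mt_tree is not None and ks_tree is not None:
            t_mt, t_ks = PhyloTree.read_newick(mt_tree), PhyloTree.read_newick(ks_tree)
            if set(t_mt.leaf_names) == set(t_ks.leaf_names):
                rf = robinson_foulds(t_mt, t_ks)

    logos = {}
    for group in sorted({e.group_label for e in catalog if e.group_label}):
        members = [e.fingerprint for e in catalog if e.group_label == group]
        logos[group] = build_logo(members, config.logo_small_sample)

    ranked = rank_candidates([c.report for c in candidates if c.report is not None])
    return MiningResult(candidates, ranked, mt_tree, ks_tree, rf, logos, config)


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", label)


def report_writer(result: MiningResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the result bundle (JSON, TSVs, Newick, logos) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    report_path = out / "report.json"
    report_path.write_text(result.to_json(), encoding="utf-8")
    written["report"] = report_path

    ranked_path = out / "ranked.tsv"
    write_ranked_tsv(result.ranked, ranked_path)
    written["ranked"] = ranked_path

    fingerprints = [c.mt_fingerprint for c in result.candidates if c.mt_fingerprint]
    fp_path = out / "fingerprints.tsv"
    write_fingerprints_tsv(fingerprints, fp_path)
    written["fingerprints"] = fp_path

    hits_path = out / "hits.tsv"
    write_hits_tsv({c.name: c.hits for c in result.candidates}, hits_path)
    written["hits"] = hits_path

    if result.mt_tree is not None:
        p = out / "mt_tree.nwk"
        p.write_text(result.mt_tree + "\n", encoding="utf-8")
        written["mt_tree"] = p
    if result.ks_tree is not None:
        p = out / "ks_tree.nwk"
        p.write_text(result.ks_tree + "\n", encoding="utf-8")
        written["ks_tree"] = p
    if result.rf_distance is not None:
        p = out / "rf.txt"
        p.write_text(f"{result.rf_distance}\n", encoding="utf-8")
        written["rf"] = p

    logo_dir = out / "logos"
    logo_dir.mkdir(exist_ok=True)
    for group, logo in result.logos.items():
        p = logo_dir / f"{_safe_name(group)}.tsv"
        write_logo_tsv(logo, p)
        written[f"logo:{group}"] = p
    return written
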