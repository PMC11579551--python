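# Methods

This note documents the models and procedures behind `mtminer`, the
parameters that matter, the design decisions that were genuinely open, and
what the synthetic fixtures do and do not establish about real data.

## Coordinate system and reference annotation

All pocket positions are expressed in **CitS numbering**: 1-based residue
indices of the citrinin synthase PksCT/CitS. The reference annotation lists
the 17 substrate-binding-pocket residues of its MT domain —
Leu1938, Phe1942, Val1954, Tyr1955, Ile1960, Asn1961, Thr2063, Asn2064,
His2067, Glu2093, Met2094, Trp2100, Val2101, Phe2105, Leu2108, Trp2111,
Gln2153 — with His2067/Glu2093 marked as the catalytic dyad. The packaged
reference *sequence* is a synthetic stand-in spanning CitS 1900–2200 with the
annotated residues planted at their positions: correctness throughout the
package is defined against the annotation (position/residue/role table), not
against any particular database record, and the real CitS sequence can be
dropped in without code changes. Validation checks (positions in range,
strictly increasing, sequence/annotation agreement, 17 positions, dyad
identity) are report entries rather than exceptions, so partially broken
annotations can be inspected.

The catalog of characterized synthases is a tab-separated table
(`name, product, n_extensions, methylated_rounds, fingerprint, group`;
rounds encoded `2+3`). Extension counts follow the ketide convention that a
pentaketide corresponds to 4 elongation rounds, so the anhydrosclerotinin B
synthase row is `n_extensions=4, methylated_rounds=2+3`. Fingerprint strings
for entries whose exact residues are not individually published are
best-effort provisional values: the facts that are published — Phe at the
CitS 2101 slot in DMOA synthases and DtbA versus Leu in 5-MOA and
5-methyl-TAL synthases; nonpolar residues at the 2094 slot in all
characterized synthases, Met there in CitS and Leu in PksAC, Glu in AsbPKS —
are enforced; the remaining slots default to the CitS residues. The same
applies to DMOA-group methylation rounds ({1,2}, provisional). Users mining
in earnest should replace these rows with curated values; the file format and
validation make that a data edit only.

## Domain location

Each domain family (SAT, KS, AT, PT, ACP, MT) is modelled as a
position-specific scoring matrix over the match columns of a seed alignment.
Columns with >50 % gaps are treated as insert columns and dropped. Match
scores are log-odds in bits,

    score(c, a) = log2((f_ca + α q_a) / ((1 + α) q_a)),

with column residue frequency `f`, Robinson–Robinson background `q`, and
pseudocount weight `α` (default 1.0; α→0 approaches the raw log-ratio with a
−20-bit floor for unseen residues, α→∞ flattens all scores to 0). This is a
deliberate simplification relative to a full profile HMM: no insert/delete
state probabilities, no forward algorithm. For envelope finding on
fixture-scale profiles it is sufficient, and a profile-HMM backend could be
substituted behind the same `DomainProfile`/`scan_protein` interface.

Scanning is local (Smith–Waterman-style) Gotoh alignment of profile columns
to the protein with affine gaps of 8 bits (open) and 1 bit (extend) against
profile columns. The dynamic program is vectorized across profile columns
per protein residue; the within-row gap state is solved with a running
maximum over `M[i,j] + j·g_e`. Hits are reported best-first: after each hit
its residues are masked and the scan repeats until the best remaining score
falls below the threshold.

**Threshold.** The default reporting threshold is 35 bits. Measured maxima of
spurious local-alignment scores on random background proteins (900 aa, six
packaged profiles) fall in the 14–20 bit range, which is the expected
`log2(K·n·m)` scale of the search space; 35 bits sits far above that noise
floor while planted domains score in the 120–950 bit range, so the margin is
wide on both sides. The threshold is configurable per scan and in the
pipeline config.

MT envelopes are extended by 30 residues toward the C terminus (clipped at
the protein end) before extraction; other families are extracted at the bare
envelope. Architecture is the hyphen-joined family string in N→C envelope
order; the NR-PKS flag requires KS, AT, PT and ACP (SAT optional). The
locator models only these six families — reducing domains (KR/DH/ER),
thioesterases and trans-acting partners are out of scope, so "no reducing
domains" is implied rather than tested. Overlapping hits of *different*
families make the architecture ambiguous; the library raises, and the
pipeline records the candidate with a null architecture instead of guessing.

## Fingerprinting

Candidate MT domains are globally aligned to the reference with Needleman–
Wunsch, BLOSUM62, and affine gaps of open 10 / extend 1 — a common pairing
for BLOSUM62; the alignment backend is Biopython's `PairwiseAligner`, whose
deterministic enumeration order fixes tie-breaking and hence reproducibility.
CitS positions map through the alignment column by column; a pocket position
aligned to a gap reads as `-` in the fingerprint and is reported with a null
candidate coordinate. Fingerprint distance is Hamming distance with
gap-vs-residue counting 1 (a deleted pocket residue is functionally a
difference) and gap-vs-gap counting 0. Mutation proposals
(`propose_site_mutation`) translate a CitS site plus target residue into
candidate coordinates, refusing identity mutations and deleted sites. The
mapping is purely alignment-based — no structural superposition — and
fingerprints are extracted from pairwise reference alignments, not from an
MSA; with the star MSA being reference-anchored, the two routes agree by
construction.

## Phylogeny and logos

The multiple alignment is a reference-anchored star alignment: each member is
pairwise-aligned to the reference and merged on reference columns, member
insertions being padded (left-justified) in all other rows. This replaces a
progressive aligner on purpose: it is deterministic, fully specified, and
exact at the pocket columns that matter here; it is *not* a general-purpose
MSA and will underperform progressive methods in highly gappy regions.

Distances: observed mismatch proportion `p` over mutually non-gap columns,
corrected with the 20-state protein Jukes–Cantor generalization
`d = −(19/20)·ln(1 − 20p/19)`, saturating to a configurable cap (default 10)
at `p ≥ 19/20`. Trees: Saitou–Nei Neighbor-Joining with the standard Q
criterion; Q ties are broken by the lexicographically smallest pair of node
labels (a node is labelled by the smallest leaf name beneath it) and negative
branch lengths are clamped to zero — both purely for determinism. Tree
similarity is the Robinson–Foulds symmetric difference over non-trivial
bipartitions. The in-package NJ and RF implementations are cross-checked in
the test suite against scikit-bio's `nj` and dendropy's bipartition
`symmetric_difference` as independent oracles.

Logos: per-column residue frequencies over non-gap symbols and information
content `IC = log2 20 − H − e_n`, with the small-sample correction
`e_n = 19/(2·ln 2·n)` applied on request and the result clamped to
`[0, log2 20]`. By default the pipeline builds logos over the 17 fingerprint
columns of each catalog group.

## Novelty mining

Residues are partitioned into four chemistry classes — nonpolar
{A,V,L,I,M,F,W,P,G}, polar {S,T,N,Q,Y,C}, acidic {D,E}, basic {K,R,H} — with
His placed among the basic residues despite its catalytic roles; the table is
a module constant and replaceable. A candidate slot is **novel** when its
residue is absent from the catalog's residues at that slot, and a
**class change** when additionally its class is absent. Gaps are novel unless
the catalog has a gap there (conservative). The ranking score is
`|novel| + w·|class change|` with default `w = 2`, so one cross-class novelty
(3 points) outranks two same-class novelties (2 points) — the discovery
signal this package formalizes was precisely a polarity change at the CitS
2094 slot. The published work gives no quantitative criterion; this score is
our formalization, and both `w` and the class table are configurable.
Methylation patterns are transferred from the minimum-distance catalog entry;
ties that disagree on the pattern return "ambiguous" with the tied set
listed, never a silent choice.

## Mass calculations

Monoisotopic masses use atomic masses pinned to 8 decimals (C 12 exactly,
H 1.00782503, N 14.00307401, O 15.99491462, S 31.97207117, P 30.97376200).
Protonation adds the **proton** mass 1.00727646 Da — not the H-atom mass —
which is what reproduces the 221.0808 calcd value for C12H12O4 [M+H]+;
[M−H]− subtracts it and [M+Na]+ adds 22.98922. No isotope patterns, average
masses, or structure-to-formula inference.

## Synthetic fixtures

The generators are pure functions of (parameters, seed), with all randomness
from `numpy.random.default_rng`.

* Background sequences draw i.i.d. from the Robinson–Robinson composition.
* MT variants copy the reference, overwrite the 17 pocket slots with a
  prescribed fingerprint (`-` deletes the site), and substitute non-pocket
  sites at a given rate (≤ 0.3), so the planted fingerprint is exact ground
  truth. The default rate in pipeline-recovery settings is 0.05 — roughly the
  divergence at which homologous domains are still trivially alignable.
* Multidomain proteins concatenate family-consensus blocks (mutated at the
  same rate) with background linkers of 20–60 residues; every interval is
  recorded as truth.
* Synthetic catalogs perturb group fingerprints per slot with probability
  `divergence`, **within the residue's chemistry class**. Within-group
  divergence emulates homologs that share a methylation program, whose pocket
  chemistry is conserved; uniform substitution would plant cross-class
  residues in the catalog itself and erase the signal the generator exists to
  provide ground truth for.

What passing these fixtures shows: the locator finds domains whose profiles
it was built from at realistic within-family divergence, coordinates map
correctly through indel-free and lightly-indeled alignments, and the decision
logic singles out planted cross-class candidates. What it does not show:
performance on real NR-PKSs with distant homology, long insertions inside
domains, degenerate ACP repeats, or fragmented gene models — the profile and
alignment layers are the components to harden for that, and the seed
alignments are replaceable data files.

## Problem sizes and numerical choices

The recovery suites use 20 seeded replicates for domain recovery and NJ
additive-tree recovery (≤ 8 leaves) and 40 replicates for full-pipeline truth
recovery, sizes at which the binomial noise on a ≥95 % criterion is already
small. DP traceback compares scores with a 1e-6 tolerance; distance-matrix
symmetry uses 1e-12; Newick round-trips preserve branch lengths to 1e-9.
Degenerate inputs (empty sequences, empty catalogs, zero-overlap alignment
rows, saturated p-distances) raise typed errors or saturate as documented
rather than returning silent defaults.

## Known limitations

* PSSM scanning has no explicit insert-state model; domains with long
  internal insertions relative to the seed may fragment into two hits.
* The star MSA is only as good as each pairwise alignment to the reference;
  it is anchored, not progressive.
* Catalog fingerprints for several entries are provisional placeholders (see
  above) — novelty calls against the packaged catalog are demonstrations,
  not biological claims.
* Nearest-neighbor pattern transfer predicts nothing about chain length or
  product structure beyond the transferred pattern, and a flagged candidate
  is a hypothesis, not an active enzyme.
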