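# mtminer

**MT-domain-focused genome mining for fungal nonreducing polyketide synthases.**

Fungal nonreducing polyketide synthases (NR-PKSs) are iterative megasynthases
with the canonical domain order SAT–KS–AT–PT–ACP, optionally carrying a
*C*-methyltransferase (MT) domain that methylates the α-carbon of the growing
β-ketoacyl chain in specific elongation rounds ("methylation programming").
The 17 substrate-binding-pocket residues of the MT domain of the citrinin
synthase CitS/PksCT (CitS numbering 1938–2153, catalytic dyad His2067/Glu2093)
correlate with a synthase's methylation pattern: reading those 17 positions out
of any candidate MT domain gives an **active-site fingerprint** that can be
compared against characterized synthases. A candidate whose pocket residue is
*unseen* at its slot — above all when it changes chemistry class, e.g. an
acidic glutamate at the CitS Met2094 slot where only nonpolar residues are
known — is a prime target for discovering new methylation programs.

`mtminer` implements that computational chain as a library and CLI:

1. **Domain location** — log-odds PSSMs built from packaged seed alignments,
   scanned with local affine-gap profile alignment (scores in bits); MT
   envelopes are extended by 30 C-terminal residues before extraction.
2. **Fingerprinting** — Needleman–Wunsch global alignment (BLOSUM62,
   gap open 10 / extend 1) to the CitS reference; CitS coordinates are mapped
   through the alignment, the 17 pocket residues read out, and point-mutation
   proposals (e.g. F→L at the CitS 2101 site) rendered in candidate
   coordinates.
3. **Comparative analysis** — reference-anchored star MSA, protein
   Jukes–Cantor distances `d = -(19/20) ln(1 - 20p/19)`, Saitou–Nei
   Neighbor-Joining trees (Newick), Robinson–Foulds tree comparison, and
   per-group sequence-logo matrices (information content
   `IC = log2 20 - H - e_n`).
4. **Novelty mining** — per-slot novelty and chemistry-class-change flags
   against a user-editable TSV catalog, nearest-neighbor methylation-pattern
   prediction, and ranking by `score = |novel| + w·|class-change|`.
5. **Mass checks** — monoisotopic masses and ESI adduct m/z values for
   product formulas.
6. **Synthetic fixtures** — deterministic generators of multidomain PKS
   proteins with planted domains and prescribed fingerprints, the ground
   truth behind the test suite.

## Worked example

Generate a synthetic input set and mine it:

```bash
mtminer fixtures --out-dir demo --seed 1 --n-proteins 2
mtminer mine demo/proteins.fasta --catalog demo/catalog.tsv --out demo_out
```

which prints:

```
fingerprints	demo_out/fingerprints.tsv
hits	demo_out/hits.tsv
logo:grpA	demo_out/logos/grpA.tsv
logo:grpB	demo_out/logos/grpB.tsv
ranked	demo_out/ranked.tsv
report	demo_out/report.json
top candidate: synthetic_pks_1 (score 3, min_distance 1)
```

Here `synthetic_pks_1` was generated with a pocket residue whose chemistry
class is absent from the demo catalog at that slot (1 novel position + 2
weighted class-change points = score 3), one substitution away from its
nearest catalog entry. `demo_out/ranked.tsv` lists every candidate with its
novelty score, nearest catalog entries and predicted methylation pattern:

```
rank	candidate	score	min_distance	nearest	novel_positions	class_change_positions	predicted_pattern
1	synthetic_pks_1	3	1	grpA_m3	2093	2093	3:1
2	synthetic_pks_2	0	0	grpA_m3			3:1
```

`report.json` carries the full machine-readable bundle, `logos/*.tsv` the
per-group frequency/information matrices, and — once three or more MT domains
are present — `mt_tree.nwk` the Neighbor-Joining tree of the extracted MT
domains.

The mass subcommand reproduces the HRMS "calcd" value for anhydrosclerotinin B
(C12H12O4, the pentaketide isocoumarin made by AsbPKS with methylation in
elongation rounds 2 and 3):

```bash
$ mtminer mass C12H12O4 --adduct "[M+H]+"
221.0808
```

And fingerprinting the packaged CitS reference against itself returns its own
pocket residues:

```bash
$ mtminer fingerprint ref.fasta
CitS_MT  LFVYINTNHEMWVFLWQ
```

## Data files

* `src/mtminer/data/cits_mt_reference.txt` — the CitS MT-domain annotation.
  The pocket/dyad position table is authoritative; the sequence is a synthetic
  stand-in spanning CitS numbering 1900–2200 and can be replaced by the real
  CitS sequence without code changes.
* `src/mtminer/data/catalog.tsv` — characterized synthases with methylation
  patterns and (partly provisional) fingerprints; tab-separated and
  user-editable.
* `src/mtminer/data/seeds/*.afa` — seed alignments behind the six domain
  profiles.

See `docs/methods.md` for the underlying models, parameter choices and
limitations.
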