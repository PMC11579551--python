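"""One-off generator for the packaged data files (reference, catalog, seeds).

Run from the repo root:  python scripts/make_data.py
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, "src")

from mtminer.composition import BACKGROUND_VECTOR  # noqa: E402
from mtminer.reference import AMINO_ACIDS  # noqa: E402

DATA = Path("src/mtminer/data")
SEEDS = DATA / "seeds"
SEEDS.mkdir(parents=True, exist_ok=True)

AA = np.array(list(AMINO_ACIDS))

POCKET = [
    (1938, "L"), (1942, "F"), (1954, "V"), (1955, "Y"), (1960, "I"),
    (1961, "N"), (2063, "T"), (2064, "N"), (2067, "H"), (2093, "E"),
    (2094, "M"), (2100, "W"), (2101, "V"), (2105, "F"), (2108, "L"),
    (2111, "W"), (2153, "Q"),
]
DYAD = {2067, 2093}
OFFSET = 1900
LENGTH = 301  # spans CitS numbering 1900-2200

rng = np.random.default_rng(421)

seq = list(rng.choice(AA, size=LENGTH, p=BACKGROUND_VECTOR))
for pos, aa in POCKET:
    seq[pos - OFFSET] = aa
seq = "".join(seq)

with open(DATA / "cits_mt_reference.txt", "w") as fh:
    fh.write("# CitS MT-domain reference annotation.\n")
    fh.write("# The sequence is a SYNTHETIC stand-in spanning CitS numbering 1900-2200;\n")
    fh.write("# the pocket/dyad annotation follows the published residue list and is the\n")
    fh.write("# authoritative part. Substitute the real CitS sequence if available.\n")
    fh.write("name = CitS_MT\n")
    fh.write(f"numbering_offset = {OFFSET}\n")
    fh.write(">CitS_MT\n")
    for i in range(0, LENGTH, 60):
        fh.write(seq[i : i + 60] + "\n")
    fh.write("[positions]\n")
    for pos, aa in POCKET:
        role = "catalytic_dyad" if pos in DYAD else "pocket"
        fh.write(f"{pos}\t{aa}\t{role}\n")

# ---------------------------------------------------------------------------
# Catalog

CATALOG = """\
# Catalog of characterized MT-domain-containing fungal NR-PKSs.
# Fingerprint strings are PROVISIONAL fixture values: facts stated in the text
# (Phe at the CitS Val2101 slot in DMOA synthases and DtbA, Leu in 5-MOA and
# 5-methyl-TAL synthases; nonpolar residues at the CitS Met2094 slot in all
# characterized synthases; Met there in CitS, Leu in PksAC; Glu in AsbPKS) are
# enforced; remaining slots default to the CitS reference residues.
# DMOA-group methylation rounds {1,2} are likewise provisional.
name	product	n_extensions	methylated_rounds	fingerprint	group
CitS	citrinin	4	1+2+3	LFVYINTNHEMWVFLWQ	citrinin
AusA	3,5-dimethylorsellinic acid	3	1+2	LFVYINSNHEMWFFLWQ	DMOA
Trt4	3,5-dimethylorsellinic acid	3	1+2	LFVYINSNHEMWFFLWQ	DMOA
AndM	3,5-dimethylorsellinic acid	3	1+2	LFVYINSNHEMWFFLWQ	DMOA
NvfA	3,5-dimethylorsellinic acid	3	1+2	LFVYINSNHEMWFFLWQ	DMOA
DtbA	2,4-dihydroxy-3,5,6-trimethylbenzaldehyde	3	1+2	LFVYVNSNHEMWFFLWQ	DMOA
FncE	5-methylorsellinic acid	3	1	LFVYINTNHEAWLFLWQ	5-MOA
MpaC	5-methylorsellinic acid	3	1	LFVYINTNHEAWLFLWQ	5-MOA
PksAC	5-methyl-triacetic acid lactone	2	1	LFVYINTNHELWLFLWQ	5-methyl-TAL
AsbPKS	anhydrosclerotinin B	4	2+3	LFVYINTNHEEWVFLWQ	AsbPKS
"""
(DATA / "catalog.tsv").write_text(CATALOG)

# ---------------------------------------------------------------------------
# Seed alignments: 4 rows each (consensus + 3 variants at 4% substitution)

FAMILY_LENGTHS = {"SAT": 80, "KS": 90, "AT": 80, "PT": 80, "ACP": 40}


def variants(consensus: str, rng, n=3, rate=0.04):
    rows = [consensus]
    for _ in range(n):
        row = list(consensus)
        for i in range(len(row)):
            if rng.random() < rate:
                choices = [a for a in AMINO_ACIDS if a != row[i]]
                row[i] = choices[rng.integers(len(choices))]
        rows.append("".join(row))
    return rows


seed_rng = np.random.default_rng(422)
for family, L in FAMILY_LENGTHS.items():
    cons = "".join(seed_rng.choice(AA, size=L, p=BACKGROUND_VECTOR))
    rows = variants(cons, seed_rng)
    with open(SEEDS / f"{family}.afa", "w") as fh:
        for i, row in enumerate(rows, 1):
            fh.write(f">{family}_seed{i}\n{row}\n")

# MT seed: the reference sequence itself plus variants
rows = variants(seq, seed_rng)
with open(SEEDS / "MT.afa", "w") as fh:
    for i, row in enumerate(rows, 1):
        fh.write(f">MT_seed{i}\n{row}\n")

print("wrote", DATA)
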