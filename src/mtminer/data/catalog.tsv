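# Catalog of characterized MT-domain-containing fungal NR-PKSs.
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
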