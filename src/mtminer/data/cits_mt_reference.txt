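# CitS MT-domain reference annotation.
# The sequence is a SYNTHETIC stand-in spanning CitS numbering 1900-2200;
# the pocket/dyad annotation follows the published residue list and is the
# authoritative part. Substitute the real CitS sequence if available.
name = CitS_MT
numbering_offset = 1900
>CitS_MT
EEGTACTVIPVHAKIIPGTKAVAKPPVQEICPRPVLGNLTRQFLSLQWEEGSTKVYDALA
INNRLARKLSSRVTKHPLRFTGDAKVGVKSGLLHAAKPNILKDGSTLVEISSGRFVVMCA
YLHSEVSTFKDDGPFVQYRNPVEEASGPSRILSVFRTGRPNSTTNMQHVVACTIILGVTD
RTQIFTAAICHNQEMNDGSAWVYQEFDNLDQWDMTKLKRLLLYTWKASNTGTRFTAELRI
GVLSVEYLPCMTNQQMASIASQNGLVKKLQNLTVCGLQDVDKTDPECKLQEGRVKGIKTE
P
[positions]
1938	L	pocket
1942	F	pocket
1954	V	pocket
1955	Y	pocket
1960	I	pocket
1961	N	pocket
2063	T	pocket
2064	N	pocket
2067	H	catalytic_dyad
2093	E	catalytic_dyad
2094	M	pocket
2100	W	pocket
2101	V	pocket
2105	F	pocket
2108	L	pocket
2111	W	pocket
2153	Q	pocket
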