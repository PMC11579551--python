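>MT_seed1
EEGTACTVIPVHAKIIPGTKAVAKPPVQEICPRPVLGNLTRQFLSLQWEEGSTKVYDALAINNRLARKLSSRVTKHPLRFTGDAKVGVKSGLLHAAKPNILKDGSTLVEISSGRFVVMCAYLHSEVSTFKDDGPFVQYRNPVEEASGPSRILSVFRTGRPNSTTNMQHVVACTIILGVTDRTQIFTAAICHNQEMNDGSAWVYQEFDNLDQWDMTKLKRLLLYTWKASNTGTRFTAELRIGVLSVEYLPCMTNQQMASIASQNGLVKKLQNLTVCGLQDVDKTDPECKLQEGRVKGIKTEP
>MT_seed2
EEGTACTVIPVHAKIIPGTKAVAKPPVQEICPRPVLGNLTRQFLSLQWEEGSTKVYDLLAINNRLARKLSSRVTKHPLRFTGDAKVGVKSGLLHAAKPNILKDGSTLVEISSGRFVVMCAYLHSEVSTFKDDGPFVQYRNPVEEASGPSRILSVFRTGRPNSSTNMQHVVACTIILGVTDRTQIFLAAICHNQEMNDGSAWVYQEFDNLDQWDMTKLKRLLLYTWKASNTGTRFTAELRIGVLSVEYLPCMTNQQMASIASQNGLVKKLQNVTVCGLQDVDKTDPECKLQEGRVKGIYTEP
>MT_seed3
EEGTACTVIPVHAKIIPGTKAVAKPPVQEICPRPVLGNLTYQFLSLQWEEGSTKVYDAEAINNRLARKLSSRVTKHPLRFTGDAKVGVKEGLLHAAKPNILKDGSTLVEISSGRFVVMCAYLHSEVSTFKDDGPFVQYRNPVEEASGPSRILSVFGTGRPNSTTNMQHVVACTIILGVTDRTQIFTAAICHNQEMNDGSAWVYQEFDNLDQWDMTKLKRLLLYTWKASNTGTRATAELRIGFLSVEYLPCMTNYQMASIASQNGLVKKLQNLTVCGLQDVDKTDPECKLQEGRVKGIKTEP
>MT_seed4
EEGTACTVIPVHAKIIPGTKAVAKPPVQEICPWPVLGNLTRQFLSLQWEMGCTKVYDALAINNRLARKLSSRVTKHPLRFTGDAKVGVKSGLLHAAKRNILKDGLTLVEISSDRFVVMCAYLHSEVSTFKDDGPFVQYRNPVVEASGPSRILSAFRTGRPNSTTNMQHYVAETIILGVTDRTQYFTAAICHNQHANDGSANVYQEFDNLDQWDMTKLKRLLLYTWKASNTGTRFTPELRIGVLSVEYLVCMTNQQMASIASQNGLVKKLQNLTVCGLQDVDKTDDECKLQEGMVKGIKTEP
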