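>PT_seed1
NAEQKRAETFPWDLSLDPELGLTIDNFVIYDLRKVSLDPSPRSNAGPGRVSSNSGDQIIIALTFPLSGPIMPSKGKINSR
>PT_seed2
NAEQKRAETFPLDLSLDPELGLTIDNFVIYDLRKVSLDPSVRSNAGPGRVSSNSGDQIIIALTFPLSGPIMPSKGKINSR
>PT_seed3
NAEQKRAETFPWDLSLDPELGLTIDNFVIYDLRKVSLDPSPRSNAGPGRVSSNSGDQIIIALTFPLSGPIMPSRGKINSR
>PT_seed4
NAEQKRAETFPWDLSLDPELGLTIDNFVIYDLRKVSLDPSPRSNAGPGSVSSNDVDQIIIALTFPLSGPIMPSKGKINSR
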