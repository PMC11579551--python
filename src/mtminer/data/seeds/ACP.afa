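>ACP_seed1
YYGSQADTTEFINDGTEELEVPAGIISKSAFTAPYPDLLQ
>ACP_seed2
YYGSQADTTEQINDGTEELEVPAGIISKSAFTAPYPDLLQ
>ACP_seed3
YYGSQADTTEFINDGTEELEVPAGIISKSAFTAPYPKLLQ
>ACP_seed4
YYGSQADTTEFINDGTEELEVPAGIISKSAFTAPYPDLLQ
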