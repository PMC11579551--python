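>SAT_seed1
NQKFELDSRVSYSKLVCRAFYRGLQFLKQSHLVRQGIYGNRTLPDICLDGSGRPTLEPKSFPFESGSLKDWTNGKAVTLA
>SAT_seed2
NQKFELDSRVSYSKLVCRAFYRGLQFLKQSHLVRQMIYGNRTLPDICLDQSGRPTLEPKSFPFESGSLKDWTFGKAVTLA
>SAT_seed3
NQKFELDSRVSYSKLVCRAFYRGLQFLKQSHLVRQGIYGNRTLPDICLDQSGRPTLEPKSFPFESGSLQDWTNGKAVTLA
>SAT_seed4
NQYFELDSRVSYSKLVCRAFYRGLQFLKQSHLVRQGIYGNRTLPDICLDGSGRPTLEPKSFPFRSGSCKDWTNGKAVTLA
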