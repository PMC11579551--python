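>AT_seed1
LYNLYAGTGVDQPNPGIREYIQPLGGESLSDNYKAGTLSSYPECVIGEKSDACMPPFNPRDLHDKEESLRDSPWEGTRTM
>AT_seed2
LYNLYAGTGVDQPNPGIREYIQPLGGESLSDNYKAGTLSSYPECVIGEKSDACNPPFNPRDLHDKEESLRDSPWEMTRTM
>AT_seed3
LYNLYAGTGVDQPNPGIREYIQPLGGESHSDHYKAGTLSSYPECVIGEKSDAQMPPFNPRDLHDKEESLRDSPWEGTRTM
>AT_seed4
LYNLYAGTGVDQPNPGIREYIQTLGGESLSDNYKAGTLSSYPECVIGEKSDACMPPFNPRDLHDKEESLWDSPWEGTRTM
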