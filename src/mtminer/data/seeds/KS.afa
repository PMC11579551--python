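>KS_seed1
QKYEGYESKWGAIAPLKGCKLFNDVQSSRNKEQQGLRLTLPTGPDTNELTTSITVVADYGIVDGQCSMGGHQGGECGAVEGNIEVVMSPA
>KS_seed2
QKYEGYESKWGIIAPLKGCKLFNDVQSSRNKEQQGLRLTLPTGPDTNELTTSITVVADYGIVDGQCSMGYHQGGECGAVEGNIIVVMSPA
>KS_seed3
QKYEGYEPKWGAIAPLYGCKPFNDVQSSRNKEQQGLRLTLPTGPDTNELTTSITVVADYGIVDGQCSMGGHQGGECGAVEGNIEVVMSPA
>KS_seed4
QKYEGYESKWGAIAPLKGCKLFNDVQSSRNKEQQGLRLTLRTGPDTNEPTTSITVVADYGIVDGFCSMGGHQGGECPAVEGNIEVVMSPA
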