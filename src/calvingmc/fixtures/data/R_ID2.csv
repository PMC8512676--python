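# Transient-to-absorbing block R of the canonical form for cow ID 2,
# as published (column of calving probabilities).
state,CALVE
L,0.001
LS,0.014
S,0
SL,0.014
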