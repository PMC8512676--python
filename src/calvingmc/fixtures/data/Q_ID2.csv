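# Transient-to-transient block Q of the canonical form for cow ID 2,
# as published (entries copy the corresponding block of P for ID 2).
state,L,LS,S,SL
L,0.952,0.047,0,0
LS,0,0,0.890,0.096
S,0,0,0.976,0.024
SL,0.957,0.029,0,0
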