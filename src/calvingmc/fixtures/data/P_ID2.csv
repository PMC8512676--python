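# Transition probability matrix for cow ID 2, transcribed at the published
# 3-decimal precision. Rows sum to 1.000 as printed.
state,L,LS,S,SL,CALVE
L,0.952,0.047,0,0,0.001
LS,0,0,0.890,0.096,0.014
S,0,0,0.976,0.024,0
SL,0.957,0.029,0,0,0.014
CALVE,0,0,0,0,1
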