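# Transition probability matrix for cow ID 11, transcribed at the published
# 3-decimal precision. The S row sums to 0.999 as printed (rounding).
state,L,LS,S,SL,CALVE
L,0.971,0.028,0,0,0.001
LS,0,0,0.884,0.093,0.023
S,0,0,0.986,0.013,0
SL,0.864,0.114,0,0,0.023
CALVE,0,0,0,0,1
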