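# Transition probability matrix for cow ID 27, transcribed at the published
# 3-decimal precision. The S row sums to 0.999 as printed (rounding).
state,L,LS,S,SL,CALVE
L,0.976,0.023,0,0,0.001
LS,0,0,0.906,0.063,0.031
S,0,0,0.990,0.009,0
SL,0.903,0.065,0,0,0.032
CALVE,0,0,0,0,1
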