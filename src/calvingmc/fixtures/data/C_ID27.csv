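# Co-occurrence counts for cow ID 27 (72 h of 1-min behavior observations,
# 25-cow dairy dataset), transcribed from the published reference matrices.
# Self-consistent with the published probability matrix at 3 decimals.
# The CALVE row uses the published absorbing convention (0,0,0,0,1).
state,L,LS,S,SL,CALVE
L,1229,29,0,0,1
LS,0,0,29,2,1
S,0,0,2972,28,1
SL,28,2,0,0,1
CALVE,0,0,0,0,1
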