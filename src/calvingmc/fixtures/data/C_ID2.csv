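# Co-occurrence counts for cow ID 2 (72 h of 1-min behavior observations,
# 25-cow dairy dataset), transcribed from the published reference matrices.
# Caution: the published LS row (0,0,65,4,1) is inconsistent with the
# published probability matrix for the same cow (65/70 = 0.929 vs the
# printed 0.890); rows other than LS normalize to the printed values.
# The CALVE row uses the published absorbing convention (0,0,0,0,1).
state,L,LS,S,SL,CALVE
L,1360,67,0,0,1
LS,0,0,65,4,1
S,0,0,2686,68,1
SL,66,3,0,0,1
CALVE,0,0,0,0,1
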