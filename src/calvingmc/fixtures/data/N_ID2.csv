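# Fundamental matrix N = (I-Q)^-1 for cow ID 2, as published at 3 decimals.
# The published table carries a fifth column of row totals (expected steps
# to calving from each start state, in minutes at 1-min steps); row totals
# agree with the sum of the first four entries to within 0.002.
# Note: N was computed by the original authors from unrounded probabilities;
# it is NOT reproducible from the 3-decimal P for ID 2 above.
state,L,LS,S,SL,ROW_TOTAL
L,372.492,17.969,657.388,17.487,1065.335
LS,356.900,18.245,667.502,17.756,1060.402
S,361.332,17.459,679.840,17.977,1076.608
SL,366.725,17.720,648.286,18.245,1050.975
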