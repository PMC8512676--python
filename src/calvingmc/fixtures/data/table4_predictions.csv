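# Published per-cow predicted calving times (hours from the start of
# observation) for the 25-cow dataset, using 72 h and 48 h of data.
# Reference actual calving time: 72 h from observation start.
cow_id,predicted_72h,predicted_48h
1,70.723,70.843
2,68.942,70.852
3,69.874,70.321
4,73.765,71.728
5,68.128,70.721
6,71.568,70.716
7,71.993,71.059
8,71.298,70.597
9,70.734,70.511
10,72.338,70.495
11,69.541,69.756
12,72.013,70.919
13,71.310,70.961
14,71.297,71.069
15,70.229,71.772
16,71.969,71.807
17,72.420,70.381
18,72.455,71.723
19,71.346,71.561
20,70.435,70.311
21,73.081,70.307
22,71.274,70.159
23,72.592,70.465
24,72.405,69.730
25,70.889,70.510
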