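sex,age_low,age_high,hf
1,6,7,0.770
1,7,8,0.767
1,8,9,0.765
1,9,10,0.762
1,10,11,0.760
0,6,7,0.773
0,7,8,0.770
0,8,9,0.768
0,9,10,0.766
0,10,11,0.764
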