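sex,age_low,age_high,hf
1,6,7,0.775
1,7,8,0.772
1,8,9,0.770
1,9,10,0.767
1,10,11,0.764
0,6,7,0.778
0,7,8,0.776
0,8,9,0.774
0,9,10,0.771
0,10,11,0.768
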