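age_lo,age_hi,weight
15,44,0.07
45,54,0.12
55,64,0.23
65,74,0.29
75,99,0.29
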