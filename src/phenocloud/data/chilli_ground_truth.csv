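date,n_leaves,stem_height_cm
2020-03-15,3,5
2020-03-19,4,7
2020-03-22,6,10
2020-03-26,7,13
2020-03-29,8,15
2020-04-02,9,20
2020-04-05,10,23
2020-04-10,11,27
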