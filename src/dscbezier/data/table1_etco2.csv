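subject,age_years,etco2_n_kpa,etco2_h_kpa
1,40,6.0,4.6
2,39,5.6,4.1
3,35,5.0,3.7
4,31,5.7,2.7
5,31,5.8,3.1
6,30,5.8,4.4
7,30,5.6,4.0
8,29,5.3,3.6
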