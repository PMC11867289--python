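subject,mtt_n_s,mtt_h_s,aoef_n,aoef_h,snr_n,snr_h,delta_n_s,delta_h_s
1,2.98,5.83,20.3,32.6,48.2,22.5,0.132,1.002
2,3.16,3.69,22.5,28.7,34.0,27.2,0.489,0.608
3,4.68,6.27,27.1,31.1,32.1,25.6,0.879,1.014
4,3.39,4.11,23.2,26.4,24.8,22.2,0.396,0.541
5,3.52,3.76,19.8,26.6,35.9,24.9,0.253,0.638
6,5.05,6.97,22.3,30.6,33.4,25.2,0.696,0.972
7,3.33,4.04,22.7,26.9,31.2,25.4,0.571,0.737
8,3.93,5.26,22.4,29.1,36.3,20.4,0.530,0.935
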