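specimen,baseline_mean_eps,baseline_sd_eps,cv_percent
A,1.771,0.185,10.47
B,1.789,0.162,9.06
C,1.646,0.112,6.79
D,1.357,0.114,8.40
E,1.386,0.127,9.16
F,1.378,0.114,8.26
G,1.134,0.062,5.48
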