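specimen,mean_ul,sd_ul,cv_percent,ci_lo_ul,ci_hi_ul
A,75.50,2.26,2.99,71.9,79.1
B,69.20,3.71,5.36,63.3,75.1
C,106.90,2.50,2.34,102.9,110.9
D,111.45,1.38,1.24,109.3,113.6
E,94.99,1.98,2.08,91.8,98.1
F,93.52,2.74,2.93,89.2,97.9
G,98.65,2.44,2.48,94.8,102.5
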