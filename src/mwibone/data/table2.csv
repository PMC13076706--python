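specimen,injected_ul,injected_uncertainty_ul,injected_scaled_ul,ct_ul,ct_scaled_ul,mwi_ul
A,402.12,115.94,67.86,326.73,55.13,75.50
B,402.12,115.94,67.86,402.12,67.86,69.20
C,628.32,181.16,106.03,452.39,76.34,106.90
D,628.32,181.16,106.03,552.92,93.31,111.45
E,502.66,144.92,84.82,376.99,63.62,94.99
F,502.66,144.92,84.82,301.59,50.89,93.52
G,402.12,115.94,67.86,376.99,63.62,98.65
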