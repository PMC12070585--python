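# Martin/Hopkins adjustable TG:VLDL-C factors, stratified by triglycerides
# (rows, mg/dL) and non-HDL cholesterol (columns, mg/dL).
# Transcribed from the published 180-cell stratification (30 TG strata x
# 6 non-HDL strata). Estimated LDL-C (mg/dL) = non-HDL - TG / factor.
tg_min,tg_max,nonhdl_lt100,nonhdl_100_129,nonhdl_130_159,nonhdl_160_189,nonhdl_190_219,nonhdl_ge220
7,49,3.5,3.4,3.3,3.3,3.2,3.1
50,56,4.0,3.9,3.7,3.6,3.6,3.4
57,61,4.3,4.1,4.0,3.9,3.8,3.6
62,66,4.5,4.3,4.1,4.0,3.9,3.9
67,71,4.7,4.4,4.3,4.2,4.1,3.9
72,75,4.8,4.6,4.4,4.2,4.2,4.1
76,79,4.9,4.6,4.5,4.3,4.3,4.2
80,83,5.0,4.8,4.6,4.4,4.3,4.2
84,87,5.1,4.8,4.6,4.5,4.4,4.3
88,92,5.2,4.9,4.7,4.6,4.4,4.3
93,96,5.3,5.0,4.8,4.6,4.5,4.4
97,100,5.4,5.1,4.8,4.7,4.5,4.3
101,105,5.5,5.2,5.0,4.7,4.6,4.5
106,110,5.6,5.3,5.0,4.8,4.6,4.5
111,115,5.7,5.4,5.1,4.9,4.7,4.5
116,120,5.8,5.5,5.2,5.0,4.8,4.6
121,126,6.0,5.5,5.3,5.0,4.8,4.6
127,132,6.1,5.7,5.3,5.1,4.9,4.7
133,138,6.2,5.8,5.4,5.2,5.0,4.7
139,146,6.3,5.9,5.6,5.3,5.0,4.8
147,154,6.5,6.0,5.7,5.4,5.1,4.8
155,163,6.7,6.2,5.8,5.4,5.2,4.9
164,173,6.8,6.3,5.9,5.5,5.3,5.0
174,185,7.0,6.5,6.0,5.7,5.4,5.1
186,201,7.3,6.7,6.2,5.8,5.5,5.2
202,220,7.6,6.9,6.4,6.0,5.6,5.3
221,247,8.0,7.2,6.6,6.2,5.9,5.4
248,292,8.5,7.6,7.0,6.5,6.1,5.6
293,399,9.5,8.3,7.5,7.0,6.5,5.9
400,13975,11.9,10.0,8.8,8.1,7.5,6.7
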