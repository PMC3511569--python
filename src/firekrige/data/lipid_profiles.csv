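lipid,glade_crown,glade_crown_se,moran_crown,moran_crown_se,glade_surface,glade_surface_se,moran_surface,moran_surface_se
11:0,0.72,0.04,0.93,0.08,0.72,0.15,0.46,0.05
12:0,2.90,0.11,2.08,0.07,3.43,0.11,2.17,0.07
14:0,4.35,0.20,2.16,0.07,3.49,0.19,2.90,0.13
15:0,1.21,0.09,1.04,0.05,0.97,0.05,1.07,0.04
15:0anteiso,3.02,0.10,2.70,0.10,2.55,0.10,3.22,0.14
15:0iso,3.13,0.10,2.91,0.09,2.86,0.09,3.90,0.13
15:1w8c,,,6.66,0.66,19.82,0.00,16.22,1.75
15:1w9c,7.75,0.88,3.72,0.36,8.64,0.60,5.64,0.38
16:0,12.15,0.31,8.35,0.20,10.25,0.32,10.03,0.19
16:02OH,1.47,0.09,2.56,0.45,1.82,0.24,1.74,0.12
16:0iso,1.61,0.06,1.37,0.05,1.45,0.05,1.68,0.06
16:1w5c,1.35,0.07,1.04,0.04,1.25,0.06,1.29,0.04
16:1w7c,5.43,0.35,4.92,0.31,4.73,0.21,5.12,0.23
17:0anteiso,1.65,0.07,1.80,0.07,1.46,0.06,1.79,0.07
cy17:0,2.55,0.17,2.26,0.20,2.45,0.14,2.59,0.13
17:0iso,0.79,0.05,0.53,0.03,0.76,0.05,0.72,0.03
17:1w8,1.28,0.17,1.29,0.09,1.68,0.13,1.21,0.08
17:1w7c,3.41,0.34,9.57,0.89,6.90,0.86,7.16,0.67
18:0,4.11,0.16,3.00,0.14,3.13,0.15,2.47,0.07
18:02OH,3.30,0.43,4.18,0.31,3.20,0.17,3.54,0.19
18:1w9c,16.10,0.88,9.08,0.50,12.89,0.67,11.45,0.56
18:2w6c,4.08,0.13,2.49,0.11,3.34,0.17,3.50,0.17
18:3w6c,2.71,0.13,1.59,0.09,2.14,0.08,2.01,0.07
19:0,0.25,0.02,1.82,0.17,0.17,0.02,0.27,0.03
cy19:0,0.47,0.03,0.40,0.04,0.09,0.03,0.49,0.04
19:1w8t,7.57,0.54,9.08,0.55,9.84,0.80,9.48,0.52
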