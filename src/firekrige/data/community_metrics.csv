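metric,glade_crown,glade_crown_se,moran_crown,moran_crown_se,glade_surface,glade_surface_se,moran_surface,moran_surface_se
abundance_nmol,205.25,15.65,374.19,25.03,363.90,28.00,301.73,17.80
fb_ratio,0.93,0.06,0.43,0.03,0.83,0.06,0.55,0.03
gm_pos,0.010,0.001,0.016,0.001,0.014,0.001,0.015,0.001
gm_neg,0.020,0.002,0.048,0.005,0.049,0.005,0.040,0.004
stress_ratio,1.04,0.03,1.12,0.03,,,1.28,0.03
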