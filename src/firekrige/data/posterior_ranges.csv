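variable,plot,trend_mean,range_mean_m,range_q5_m,range_q95_m,sill_mean,nugget_mean,nugget_ratio_mean,cv_r2
abundance_nmol,glade_crown,204.3,4.5,0.0,132.9,10864,7672.2,0.79,0.94
abundance_nmol,moran_crown,373.3,1.5,0.0,100.5,29362,19549.9,0.73,0.98
abundance_nmol,glade_surface,363.5,3.0,0.0,142.2,39545,27732.2,0.80,0.93
abundance_nmol,moran_surface,313.5,78.9,7.8,145.2,20413,16429.6,0.83,0.56
fb_ratio,glade_crown,0.9,10.5,1.8,27.6,0.14,0.10,0.78,0.89
fb_ratio,moran_crown,0.4,3.6,0.3,9.6,0.03,0.02,0.72,0.97
fb_ratio,glade_surface,0.8,1.5,0.0,6.0,0.14,0.09,0.72,0.98
fb_ratio,moran_surface,0.5,5.1,1.2,21.6,0.03,0.02,0.75,0.94
net_n_mineralization,glade_crown,17.1,13.8,6.9,27.0,1101,686.2,0.65,0.87
net_n_mineralization,moran_crown,4.5,2.4,0.0,13.8,792,540.6,0.74,0.97
net_n_mineralization,glade_surface,17.1,1.5,0.0,10.5,558,379.8,0.73,0.98
net_n_mineralization,moran_surface,22.1,1.8,0.0,6.0,358,240.4,0.72,0.98
vegetative_cover,glade_crown,29.5,9.9,4.2,26.1,413,282.38,0.73,0.89
vegetative_cover,moran_crown,23.6,1.5,0.0,4.8,285,190.96,0.72,0.98
vegetative_cover,glade_surface,30.2,1.8,0.0,9.9,226,153.97,0.74,0.98
vegetative_cover,moran_surface,24.4,4.2,0.3,23.1,273,195.02,0.77,0.95
detrital_abiotic_cover,glade_crown,70.4,9.9,4.2,26.1,413,282.4,0.73,0.89
detrital_abiotic_cover,moran_crown,76.3,1.5,0.0,4.8,285,191.0,0.72,0.98
detrital_abiotic_cover,glade_surface,69.8,1.8,0.0,9.9,226,154.0,0.74,0.98
detrital_abiotic_cover,moran_surface,75.5,4.2,0.3,23.1,273,195.0,0.77,0.95
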