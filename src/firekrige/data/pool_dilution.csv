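plot,gross_nitrification,gross_nitrification_se,nh4_consumption,nh4_consumption_se,no3_consumption,no3_consumption_se,net_nh4,net_nh4_se,net_no3,net_no3_se
glade_crown,0.06,0.02,0.44,0.07,0.09,0.02,-0.24,0.04,-0.03,0.01
moran_crown,0.38,0.09,0.83,0.14,0.61,0.10,-0.47,0.11,-0.24,0.13
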