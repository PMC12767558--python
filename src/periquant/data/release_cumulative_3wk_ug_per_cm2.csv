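# Cumulative growth-factor release over 3 weeks, mean (SD), ug/cm^2.
# Empty fields: condition not loaded with that growth factor.
condition,bmp2_mean,bmp2_sd,vegf_mean,vegf_sd
Col-Hep/VEGF+BMP-2,1.19,0.30,1.57,0.75
Col-Hep/VEGF,,,1.35,0.16
Col-Hep/BMP-2,1.59,0.14,,
Col-Hep,,,,
Ti/VEGF+BMP-2,0.89,0.66,0.16,0.05
Ti/VEGF,,,0.27,0.02
Ti/BMP-2,0.36,0.03,,
Ti Control,,,,
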