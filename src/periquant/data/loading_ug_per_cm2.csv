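# Growth-factor loading by supernatant depletion, mean (SD), ug/cm^2.
# Empty fields: condition not loaded with that growth factor.
condition,bmp2_mean,bmp2_sd,vegf_mean,vegf_sd
Col-Hep/VEGF+BMP-2,4.30,0.77,4.02,0.43
Col-Hep/VEGF,,,4.48,0.67
Col-Hep/BMP-2,5.69,1.08,,
Col-Hep,,,,
Ti/VEGF+BMP-2,2.56,1.21,4.57,0.40
Ti/VEGF,,,4.37,1.23
Ti/BMP-2,2.26,0.77,,
Ti Control,,,,
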