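species,functional_group,size_value,size_metric,size_ci95,mass_mg_afdw,mass_ci95,I_mW,I_ci95,density_ind_m2,Itot_mW_m2,Itot_ci95,Rtot_g_m2,Rtot_ci95
A. marina,deep,160,wet_weight_mg,8,16.34,1.68,0.07,0.02,32,2.32,0.69,21.53,6.43
A. marina,deep,160,wet_weight_mg,8,16.34,1.68,0.07,0.02,64,4.64,1.38,38.58,2.43
A. marina,deep,160,wet_weight_mg,8,16.34,1.68,0.07,0.02,95,6.95,2.07,42.26,5.75
A. marina,deep,160,wet_weight_mg,8,16.34,1.68,0.07,0.02,127,9.27,2.77,39.41,0.84
A. marina,deep,1500,wet_weight_mg,75,169.04,20.57,0.51,0.13,32,16.11,4.02,35.64,4.86
A. marina,deep,1500,wet_weight_mg,75,169.04,20.57,0.51,0.13,64,32.22,8.04,41.43,2.13
A. marina,deep,1500,wet_weight_mg,75,169.04,20.57,0.51,0.13,95,48.33,12.07,48.88,6.7
A. marina,deep,1500,wet_weight_mg,75,169.04,20.57,0.51,0.13,127,64.44,16.09,60.88,23.3
A. marina,deep,8000,wet_weight_mg,200,970.27,148.4,2.16,0.49,32,68.69,15.65,45.51,2.86
A. marina,deep,8000,wet_weight_mg,200,970.27,148.4,2.16,0.49,64,137.37,31.29,42.89,3.36
A. marina,deep,8000,wet_weight_mg,200,970.27,148.4,2.16,0.49,95,206.06,46.94,145.29,100.92
A. alba,intermediate_IBB,15,shell_length_mm,0.5,17.29,4.27,0.1,0.03,45,4.25,1.32,36.81,8.18
A. alba,intermediate_IBB,15,shell_length_mm,0.5,17.29,4.27,0.1,0.03,95,9.1,2.82,37.29,0.31
L. balthica,intermediate_IBB,15,shell_length_mm,0.5,33.98,4.57,0.16,0.04,33,5.02,1.12,34.24,2.92
L. balthica,intermediate_IBB,15,shell_length_mm,0.5,33.98,4.57,0.16,0.04,64,10.03,2.24,36.13,5.17
L. balthica,intermediate_IBB,15,shell_length_mm,0.5,33.98,4.57,0.16,0.04,191,30.09,6.71,41.05,0.23
L. balthica,intermediate_IBB,15,shell_length_mm,0.5,33.98,4.57,0.16,0.04,382,60.19,13.43,49.67,7.66
S. plana,intermediate_IBB,15,shell_length_mm,0.5,17.98,2.61,0.1,0.02,64,6.24,1.46,44.96,9.22
S. plana,intermediate_IBB,15,shell_length_mm,0.5,17.98,2.61,0.1,0.02,382,37.46,8.76,88.84,87.85
S. plana,intermediate_IBB,35,shell_length_mm,0.5,166.26,17.99,0.51,0.1,64,32.74,6.46,63.32,40.89
R. philippinarum,intermediate_IBB,25,shell_length_mm,0.5,159.54,46.73,0.5,0.17,32,15.87,5.33,34,14.53
C. edule,shallow,10,shell_length_mm,0.5,10.52,2.42,0.02,0.03,95,6.28,7.89,37.26,7.89
C. edule,shallow,10,shell_length_mm,0.5,10.52,2.42,0.02,0.03,191,12.57,1.15,43.63,1.15
C. edule,shallow,10,shell_length_mm,0.5,10.52,2.42,0.02,0.03,382,25.13,10.34,59.09,10.34
C. edule,shallow,20,shell_length_mm,0.5,99.14,12.52,0.07,0.1,32,11.14,9.01,44.04,9.01
C. edule,shallow,20,shell_length_mm,0.5,99.14,12.52,0.07,0.1,64,22.27,0.4,44.65,0.4
C. edule,shallow,20,shell_length_mm,0.5,99.14,12.52,0.07,0.1,127,44.55,2.23,45.04,2.23
C. edule,shallow,20,shell_length_mm,0.5,99.14,12.52,0.07,0.1,255,89.09,34.37,71.37,34.37
C. edule,shallow,35,shell_length_mm,0.5,606.31,70.85,0.27,0.31,13,17.17,0.11,36.61,0.11
C. edule,shallow,35,shell_length_mm,0.5,606.31,70.85,0.27,0.31,32,42.92,11.72,48.95,11.72
C. edule,shallow,35,shell_length_mm,0.5,606.31,70.85,0.27,0.31,64,85.84,6.63,49.55,6.63
C. edule,shallow,35,shell_length_mm,0.5,606.31,70.85,0.27,0.31,191,257.51,20.26,122.62,20.26
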