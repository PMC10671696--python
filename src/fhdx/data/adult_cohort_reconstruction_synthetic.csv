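id,role,age_years,sex,fam_pcvd,fam_hyperlipidemia,fam_fh_diagnosis,fam_relative_tendon_xanthoma,fam_child_high_ldl,pers_premature_cad,pers_premature_cerebral_peripheral,sign_tendon_xanthoma,sign_arcus_under_45,sign_xanthelasma,pre_tc,pre_ldl,pre_hdl,pre_tg,on_ldl,peak_ldl,regimen,variant_detected,variants,excluded_alternative_diagnosis
P01,proband,52,M,1,1,1,0,0,0,0,1,0,0,10.58,9,,,4.05,9.47,rosuvastatin:20,1,c.986 G>A|c.1055 G>A,0
P02,proband,44,F,1,1,1,0,0,0,0,0,1,0,10.78,9.2,,,4.14,9.67,rosuvastatin:20;ezetimibe:10,1,c.1241 T>G|c.1247 G>A,0
P03,proband,47,M,1,1,1,0,0,0,0,0,0,1,10.98,9.4,,,3.95,9.87,atorvastatin:80;ezetimibe:10,1,c.268 G>A,0
P04,proband,55,F,1,1,1,0,0,0,0,0,0,0,11.18,9.6,,,4.32,10.07,rosuvastatin:20,1,c.301 G>A,0
P05,proband,60,M,1,1,1,0,0,0,0,0,0,0,11.38,9.8,,,4.9,10.27,atorvastatin:40,1,c.523 G>A,0
P06,proband,41,F,1,1,1,0,0,0,0,0,0,0,11.58,10,,,4.5,10.47,rosuvastatin:20;ezetimibe:10,1,c.769 C>T,0
P07,proband,38,M,1,1,1,0,0,0,0,0,0,0,11.78,10.2,,,4.59,10.67,rosuvastatin:40,1,c.1060+2 T>C,0
P08,proband,49,F,1,1,1,0,0,0,0,0,0,0,11.98,10.4,,,4.68,10.87,atorvastatin:80,1,c.1216 C>A,0
P09,proband,58,M,1,1,1,0,0,0,0,0,0,0,12.18,10.6,,,4.77,11.07,rosuvastatin:20,1,c.1285 G>A,0
P10,proband,45,F,1,1,1,0,0,0,0,0,0,0,12.38,10.8,,,4.32,11.27,rosuvastatin:40;ezetimibe:10,1,c.1297 G>C,0
P11,proband,50,M,1,1,1,0,0,0,0,0,0,0,10.08,8.5,,,4.25,8.97,atorvastatin:40,1,c.1448 G>A,0
P12,proband,43,F,1,1,1,0,0,0,0,0,0,0,11.5,9.92,,,4.46,10.39,rosuvastatin:20,1,c.1469 G>A,0
P13,proband,35,M,0,1,1,0,0,0,0,0,0,0,7.18,5.6,,,2.8,6.07,atorvastatin:40,1,c.1586+5 G>C,0
P14,proband,38,F,0,1,1,0,0,0,0,0,0,0,7.48,5.9,,,2.95,6.37,atorvastatin:40,1,c.1706-1 G>C,0
P15,proband,42,M,0,1,1,0,0,0,0,0,0,0,7.78,6.2,,,2.79,6.67,rosuvastatin:20,1,c.1731 G>C,0
P16,proband,35,F,0,0,0,0,0,0,0,0,0,0,6.78,5.2,,,3.38,5.67,simvastatin:10,1,c.1765 G>A,0
P17,proband,44,M,0,1,1,0,0,0,0,0,0,0,10.8,7.5,,,5.25,11,simvastatin:20,0,,0
P18,proband,51,F,0,1,1,0,0,0,0,0,0,0,10.2,6.8,,,4.76,10.5,simvastatin:20,0,,0
P19,proband,44,M,0,1,1,0,0,0,0,0,0,0,9,5.29,,,2.38,10,atorvastatin:40,0,,0
C01,cascade_relative,35,F,1,1,1,0,0,0,0,0,0,0,10.45,8,,,4,8.17,rosuvastatin:20,1,c.1241 T>G,0
C02,cascade_relative,40,M,1,1,1,0,0,0,0,0,0,0,10.45,8,,,4,8.17,rosuvastatin:20,1,c.1241 T>G,0
C03,cascade_relative,45,F,1,1,1,0,0,0,0,0,0,0,10.45,8,,,4,8.17,rosuvastatin:20,1,c.1731 G>C,0
C04,cascade_relative,50,M,1,1,1,0,0,0,0,0,0,0,10.45,8,,,4,8.17,rosuvastatin:20,1,c.1731 G>C,0
C05,cascade_relative,55,F,1,1,1,0,0,0,0,0,0,0,10.45,8,,,4,8.17,rosuvastatin:20,1,c.1448 G>A,0
C06,cascade_relative,48,M,1,1,1,0,0,0,0,0,0,0,10.31,7.6,,,,7.77,,1,c.1448 G>A,0
C07,cascade_relative,25,F,0,1,1,0,0,0,0,0,0,0,6.7,5.2,,,2.6,5.37,atorvastatin:40,1,c.986 G>A,0
C08,cascade_relative,22,M,0,1,1,0,0,0,0,0,0,0,5.8,4.4,,,2.2,4.57,rosuvastatin:10,1,c.1241 T>G,0
C09,cascade_relative,24,F,0,1,1,0,0,0,0,0,0,0,5.8,4.4,,,2.2,4.57,rosuvastatin:10,1,c.1880 C>T,0
C10,cascade_relative,26,M,0,1,1,0,0,0,0,0,0,0,5.8,4.4,,,,4.57,,1,c.1765 G>A,0
C11,cascade_relative,25,F,0,1,1,0,0,0,0,0,0,0,5.9,4.7,,,,,none,0,,0
C12,cascade_relative,27,M,0,0,1,0,0,0,0,0,0,0,5,3.66,,,,,none,0,,0
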