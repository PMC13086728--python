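run_id,PLGA,PVA,Vaq,EE_pct,EE_pct_sd,size_nm,size_nm_sd,Q8h_pct,Q8h_pct_sd,Q24_ug_cm2,Q24_ug_cm2_sd
P1,50,2,0.5,95.29,2.67,185.51,15.14,55.97,8.19,515.61,29.41
P2,75,1.5,1,84.37,5.03,393.50,21.00,79.97,14.46,211.73,9.72
P3,75,1,0.75,94.49,6.84,420.04,19.41,24.76,5.22,209.56,11.69
P4,50,1,0.5,74.42,2.89,311.61,22.95,46.85,7.13,398.84,12.91
P5,50,1.5,0.75,61.37,3.89,346.74,11.32,43.53,5.23,273.15,13.47
P6,50,1,1,69.55,4.27,505.43,25.28,50.16,7.76,170.57,10.36
P7,25,1,0.75,66.72,7.02,345.67,10.18,37.31,4.41,313.71,16.84
P8,25,1.5,0.5,89.04,9.00,204.36,13.07,77.37,12.35,495.97,20.12
P9,25,1.5,1,51.93,0.70,299.42,9.01,80.70,16.32,403.41,17.56
P10,50,1.5,0.75,62.79,1.23,348.47,17.1,46.22,7.68,256.66,15.58
P11,75,1.5,0.5,92.50,6.89,456.35,28.34,66.22,9.55,192.13,8.77
P12,75,2,0.75,93.47,4.02,329.23,8.35,57.15,6.45,372.83,14.33
P13,25,2,0.75,80.85,0.53,241.51,6.35,70.14,9.78,471.12,23.76
P14,50,2,1,72.38,8.05,353.00,14.00,74.51,13.33,214.63,18.28
P15,50,1.5,0.75,64.66,3.18,347.14,20.10,48.61,6.87,271.91,16.29
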