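formulation,lag_min,lag_min_sd,jss_ug_cm2_h,jss_sd,kp_cm_h,kp_sd,ei
P1,24.94,3.52,54.15,2.84,0.0541,0.0014,5.54
P2,80.69,4.23,22.49,0.86,0.0225,0.0016,2.30
P3,83.02,5.46,23.52,3.42,0.0235,0.0017,2.41
P4,51.05,2.33,44.06,0.99,0.0441,0.0007,4.51
P5,69.31,4.66,32.74,5.23,0.0327,0.0013,3.35
P6,93.62,6.14,15.03,3.87,0.0150,0.0011,1.54
P7,66.52,10.51,26.54,4.75,0.0265,0.0008,2.72
P8,38.53,2.73,55.16,6.12,0.0552,0.0015,5.65
P9,50.50,9.81,40.66,1.96,0.0407,0.0027,4.16
P10,74.27,8.74,27.60,4.57,0.0276,0.0019,2.82
P11,90.38,11.45,19.30,2.26,0.0193,0.0016,1.98
P12,60.39,5.77,38.63,5.94,0.0386,0.0040,3.95
P13,47.87,6.01,41.79,6.12,0.0418,0.0031,4.28
P14,79.65,7.29,23.44,3.43,0.0234,0.0054,2.40
P15,72.31,8.74,30.11,4.178,0.0301,0.0035,3.08
control,100.20,22.66,9.77,2.51,0.0098,0.0009,
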