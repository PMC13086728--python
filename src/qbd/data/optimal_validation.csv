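response,actual,actual_sd,predicted
EE_pct,98.04,3.71,99.87
size_nm,174.82,11.45,185.51
Q8h_pct,78.61,5.33,80.16
Q24_ug_cm2,515.69,16.39,522.31
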