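concentration_mg_per_ml,inhibition_pct,sd_pct
1.50,25,3
1.88,28,1
3.00,36.6,0.3
3.75,50,3
7.50,90.5,0.3
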