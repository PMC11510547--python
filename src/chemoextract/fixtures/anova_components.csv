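source,df,sum_sq
regression,6,253.357
residual,26,41.066
lack_of_fit,18,36.421
pure_error,8,5.006
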