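sulfate_group,sulfate_range_mM,d13ch4_permil,d13ch4_se,d13co2_permil,d13co2_se
low,0.5-4,-61.5,1.7,-17.0,3.4
high,10-25,-50.7,1.2,-22.8,1.9
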