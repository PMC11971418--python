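zone,eps_max,t_opt,vpd0
Bwk,3.820,29.875,2.689
BSk,3.997,19.683,2.996
Csa,2.596,14.386,0.453
Cfa,3.101,28.674,0.871
Cfb,3.075,16.780,2.082
Dfa,3.156,29.996,2.863
Dfb,2.349,12.988,2.312
Dfc,1.875,29.939,1.946
Default,3.364,29.995,2.380
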