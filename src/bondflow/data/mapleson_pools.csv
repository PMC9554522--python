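pool,V_p,delta_p,lambda_p
viscera,6.2,0.399,0.46
lean,39.2,0.364,0.46
fat,12.2,0.111,1.40
shunt,0.0,0.126,0.46
white_matter,0.0007,0.000014,0.46
grey_matter,0.0007,0.000055,0.46
kidney,0.0007,0.000274,0.46
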