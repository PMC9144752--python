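name,parameter_set,D,R,s,a,r1,r2
CIA,modified,15.3,12,0.4,5.40,5.70,1.86
CIA,official,15.3,12,0.75,5.5,7.0,1.75
CIB,modified,20.2,12,0.6,6.10,7.80,1.78
CIB,official,20.2,12,0.75,7.0,11.75,1.75
COB,modified,19.8,12,1.0,5.18,2.28,3.055
COB,official,19.8,12,1.0,6.0,3.5,3.5
COC,modified,25.4,14,1.0,8.21,2.48,2.742
COC,official,25.4,14,1.0,10.2,4.2,3.5
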