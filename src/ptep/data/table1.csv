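name,accum_label,particle_type,gram,motile,size_um,shape,zeta_mV,Saccum_per_s,Aaccum_um2
PS1.1,No,Synthetic microspheres,synthetic,False,1.1,sphere,-6.43,0.33,210
SAg,No,Gram(+) bacteria,+,False,0.6 to 12,chain,-9.24,0.25,1328
SEp,Weak,Gram(+) bacteria,+,False,0.5 to 1,cocci,-12.1,0.90,1472
SAu,Weak,Gram(+) bacteria,+,False,0.5 to 1.5,cocci,-14.7,1.18,1739
EC,Strong,Gram(-) bacteria,-,True,0.5 to 2 x 2 to 6,rod,-15.9,2.53,1605
KP,Strong,Gram(-) bacteria,-,False,0.5 x 2,rod,-22.9,5.90,3250
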