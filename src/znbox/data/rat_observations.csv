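compartment,delta66Zn,ci_halfwidth,n,excluded
diet,0.42,0.08,5,0
plasma,0.36,0.2,1,0
liver,-0.48,0.12,2,0
rbc,0.47,0.03,2,0
muscle,-0.21,0.21,2,0
bone,0.37,0.12,3,0
integument,0.08,0.2,1,0
feces,0.44,0.14,2,0
kidney,-0.12,0.12,2,1
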