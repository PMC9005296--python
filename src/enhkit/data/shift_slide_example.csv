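property,AA,AC,AG,AT,CA,CC,CG,CT,GA,GC,GG,GT,TA,TC,TG,TT
Shift,0.0,0.126,0.0,-1.019,-0.861,0.0,0.0,0.0,0.0,0.0,0.0,0.0,-2.243,0.126,0.0,1.587
Slide,0.0,1.289,0.0,2.513,-0.623,0.0,0.0,0.0,0.0,0.0,0.0,0.0,-1.511,-0.394,0.0,0.111
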