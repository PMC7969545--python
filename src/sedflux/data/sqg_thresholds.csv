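element,lel,erl,tas
Cr,26,80,100
Ni,16,30,200
Cu,16,70,100
Zn,120,120,200
As,6,33,5
Cd,0.6,5,1
Pb,31,35,60
Hg,0.2,0.15,0.5
V,,,
Co,,,
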