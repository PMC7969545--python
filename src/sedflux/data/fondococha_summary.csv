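element,conc_pre1950,conc_post1950,conc_factor,conc_recent,flux_pre1950,flux_post1950,flux_factor,flux_recent
Cr,16.7,15.1,0.9,16.53,1.15,2.83,2.45,3.32
Ni,8.82,6.97,0.79,6.65,0.61,1.3,2.14,1.34
Cu,24.67,24.79,1,33.4,1.71,4.64,2.72,6.71
Zn,76.29,74.05,0.97,75.97,5.29,13.87,2.62,15.27
As,14.16,15.83,1.12,18.93,0.98,2.95,3.01,3.8
Cd,0.42,0.37,0.87,0.29,0.03,0.07,2.3,0.06
Pb,22.73,22.68,1,23.93,1.58,4.23,2.69,4.8
Hg,0.094,0.153,1.63,0.17,0.006,0.028,4.39,0.03
C,79.95,102.44,1.3,117.89,6.07,19.04,3.1,23.7
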