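element,conc_pre1950,conc_post1950,conc_factor,conc_recent,flux_pre1950,flux_post1950,flux_factor,flux_recent
Cr,27.1,29.8,1.1,34.41,8.68,22.57,2.6,26.92
Ni,8.1,8.93,1.1,10.02,2.59,6.75,2.61,7.83
Cu,31.73,40.67,1.28,46.35,10.17,31.09,3.06,36.23
Zn,178.8,226.41,1.27,253.68,57.25,174.01,3.04,198.35
As,25.87,35.84,1.39,42.23,8.29,27.67,3.34,32.96
Cd,2.11,2.61,1.24,2.94,0.67,1.98,2.93,2.3
Pb,76.82,141.94,1.85,173.37,24.63,110.55,4.49,135.46
Hg,0.111,0.163,1.47,0.19,0.036,0.122,3.39,0.15
C,101.69,87.45,0.9,95.22,53.84,70.8,1.3,43.63
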