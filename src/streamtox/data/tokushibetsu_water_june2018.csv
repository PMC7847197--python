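site,status,Cu,Cd,Pb,Zn,hardness
S1a,contaminated,1.0,0.13,0.69,24.0,13
S1b,contaminated,1.1,0.16,0.71,27.5,13
S2,contaminated,0.8,0.17,0.25,25.9,14
S3,contaminated,0.5,0.07,0.23,11.5,13
S4,contaminated,0.3,<0.005,0.05,4.8,14
R1,reference,0.1,<0.005,0.09,25.3,10
R2,reference,0.1,<0.005,<0.005,0.1,11
R3,reference,0.1,<0.005,0.04,0.1,11
R4,reference,0.1,<0.005,0.03,0.3,12
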