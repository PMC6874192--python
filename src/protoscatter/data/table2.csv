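patient,field,site,csf,psf,cpsf
A,1,brain,1.018,1.010,1.028
B,1,brain,1.001,1.002,1.003
C,1,brain,1.000,1.004,1.004
D,1,brain,1.006,0.993,0.999
E,1,brain,1.006,0.986,0.992
F,1,pancreas,1.010,0.998,1.008
F,2,pancreas,1.018,1.005,1.023
G,1,pancreas,1.014,0.993,1.007
H,1,pancreas,1.005,1.000,1.005
I,1,pancreas,1.009,1.004,1.013
I,2,pancreas,1.025,0.981,1.006
J,1,pancreas,1.020,1.020,1.040
J,2,pancreas,1.019,1.019,1.038
K,1,prostate,1.010,1.013,1.023
K,2,prostate,1.014,1.010,1.024
L,1,prostate,1.028,1.004,1.032
L,2,prostate,1.038,1.005,1.043
M,1,prostate,1.006,1.014,1.020
M,2,prostate,1.006,1.008,1.014
N,1,prostate,1.002,1.002,1.004
N,2,prostate,1.017,1.008,1.025
O,1,lung,1.044,0.971,1.014
P,1,lung,1.015,0.977,0.992
Q,1,lung,1.008,1.000,1.008
R,1,lung,1.020,0.947,0.966
S,1,lung,1.007,0.944,0.951
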