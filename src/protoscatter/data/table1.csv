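site,field_id,tps_csf,mc_csf,tps_psf,mc_psf
brain,1,1.010,1.024,1.003,1.030
brain,2,1.002,1.000,1.002,1.000
brain,3,1.004,1.000,1.005,1.028
pancreas,1,1.000,1.002,1.002,1.005
pancreas,2,1.033,1.030,1.002,1.014
pancreas,3,1.011,1.017,1.002,1.017
prostate,1,1.016,1.006,1.023,1.025
prostate,2,1.010,1.010,1.013,1.025
prostate,3,1.003,1.002,1.017,1.022
lung,1,1.012,1.026,0.961,0.960
lung,2,1.009,1.014,0.920,0.947
lung,3,1.020,1.017,0.919,0.951
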