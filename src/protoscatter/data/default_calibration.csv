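hu,rsp,density,inv_x0
-1000,0.001,0.0012,0.0012
-650,0.30,0.30,0.30
-500,0.45,0.45,0.45
0,1.00,1.00,1.00
125,1.07,1.09,1.09
500,1.28,1.35,2.295
1245,1.60,1.85,3.145
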