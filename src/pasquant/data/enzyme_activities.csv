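id,age,sex,pk_high_affinity,aldolase,adenylate_kinase,tpi,hexokinase
219,19,f,0.69,0.27,4.87,0.19,20.52
309,21,f,0.12,0.51,4.94,0.04,21.72
308,23,m,0.34,0.59,6.75,0.06,5.81
214,29,m,0.46,0.27,4.90,0.20,7.03
307,44,m,0.48,0.76,7.70,0.11,18.54
302,59,m,1.23,1.74,28.33,0.34,22.43
305,62,f,0.65,1.00,14.48,0.20,11.28
303,69,m,0.81,1.21,11.41,0.17,9.58
221,71,f,0.37,0.57,12.33,0.22,6.23
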