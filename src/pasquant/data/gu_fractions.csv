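subset,group,mean_pct,sd_pct,n
gu_high,young,1.7,1.5,3
gu_high,old,5.4,3.5,7
gu_inter,young,66.5,36.9,3
gu_inter,old,66.4,22.5,7
gu_low,young,31.8,36.7,3
gu_low,old,28.2,21.7,7
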