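case_id,age_ob,igm_pct,igg_pct,iga_pct,expected
1,23,17,73,29,severe
2,19,36,58,17,less severe
3,3,81,14,62,severe
4,120,81,7,35,severe
5,23,41,7,35,less severe
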