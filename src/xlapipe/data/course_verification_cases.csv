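case_id,age_ob,igm_pct,igg_pct,iga_pct,expected
1,19,12,19,17,very severe
2,19,12,73,17,severe
3,47,12,73,17,severe
4,47,92,73,17,less severe
5,23,92,73,17,severe
6,23,92,73,46,less severe
7,23,92,73,76,severe
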