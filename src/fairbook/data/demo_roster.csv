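patient_id,group,income_index,employed,married,show_prob
a,nonB,1.2,1,1,0.90
b,nonB,0.9,1,0,0.90
c,B,-0.6,0,1,0.45
d,B,-0.8,0,0,0.40
e,B,-1.1,0,1,0.35
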