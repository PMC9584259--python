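patient_id,slot_index,priority
a,1,1
d,2,1
e,2,2
c,3,1
b,4,1
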