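subject_id	group
R01	high
R02	high
R03	high
R04	high
R05	high
R06	high
R07	low
R08	low
R09	low
R10	low
R11	low
R12	low
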