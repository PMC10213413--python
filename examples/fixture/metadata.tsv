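sample_id	subject_id	group	sex
nasal-R01	R01	high	M
nasal-R02	R02	high	F
nasal-R03	R03	high	M
nasal-R04	R04	high	F
nasal-R05	R05	high	M
nasal-R06	R06	high	F
nasal-R07	R07	low	M
nasal-R08	R08	low	F
nasal-R09	R09	low	M
nasal-R10	R10	low	F
nasal-R11	R11	low	M
nasal-R12	R12	low	F
colonic-R01	R01	high	M
colonic-R02	R02	high	F
colonic-R03	R03	high	M
colonic-R04	R04	high	F
colonic-R05	R05	high	M
colonic-R06	R06	high	F
colonic-R07	R07	low	M
colonic-R08	R08	low	F
colonic-R09	R09	low	M
colonic-R10	R10	low	F
colonic-R11	R11	low	M
colonic-R12	R12	low	F
lung-R01	R01	high	M
lung-R02	R02	high	F
lung-R03	R03	high	M
lung-R04	R04	high	F
lung-R05	R05	high	M
lung-R06	R06	high	F
lung-R07	R07	low	M
lung-R08	R08	low	F
lung-R09	R09	low	M
lung-R10	R10	low	F
lung-R11	R11	low	M
lung-R12	R12	low	F
colon-R01	R01	high	M
colon-R02	R02	high	F
colon-R03	R03	high	M
colon-R04	R04	high	F
colon-R05	R05	high	M
colon-R06	R06	high	F
colon-R07	R07	low	M
colon-R08	R08	low	F
colon-R09	R09	low	M
colon-R10	R10	low	F
colon-R11	R11	low	M
colon-R12	R12	low	F
muscle-R01	R01	high	M
muscle-R02	R02	high	F
muscle-R03	R03	high	M
muscle-R04	R04	high	F
muscle-R05	R05	high	M
muscle-R06	R06	high	F
muscle-R07	R07	low	M
muscle-R08	R08	low	F
muscle-R09	R09	low	M
muscle-R10	R10	low	F
muscle-R11	R11	low	M
muscle-R12	R12	low	F
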