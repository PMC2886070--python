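rule_id	locus	symbol	layer	contrast	direction	prediction_type	species	versus	note
aop2_t_ch	At4g03050	AOP2	T	CH_vs_EX+NZ	up	alkenyl_higher	CH	EX,NZ
aop3_t_ch	At4g03060	AOP3	T	CH_vs_EX+NZ	up	hydroxyalkyl_higher	CH	EX,NZ	possible cross-hybridization artefact of AOP2 on the AOP3 probe
mam1_t_ch	At5g23010	MAM1	T	CH_vs_NZ	up	c4_higher	CH	NZ
mam1_t_ex	At5g23010	MAM1	T	EX_vs_NZ	up	c4_higher	EX	NZ
esm1_t_ex	At3g14210	ESM1	T	EX_vs_CH+NZ	up	isothiocyanates	EX	rest
esm1_t_nz	At3g14210	ESM1	T	NZ_vs_CH+EX	down	nitriles	NZ	rest
mami_p_ch	At2g43100	MAM-I	P	CH_vs_EX	up	c4_higher	CH	EX
mami_p_nz	At2g43100	MAM-I	P	NZ_vs_CH+EX	up	c4_higher	NZ	CH,EX
mamd1_p_nz	At5g14200	MAM-D	P	NZ_vs_CH+EX	up	c4_higher	NZ	CH,EX
mamd2_p_nz	At1g31180	MAM-D	P	NZ_vs_CH+EX	up	c4_higher	NZ	CH,EX
esp_p_nz	At1g54040	ESP	P	NZ_vs_CH+EX	up	nitriles	NZ	rest
esp_p_ex	At1g54040	ESP	P	EX_vs_CH+NZ	down	isothiocyanates	EX	rest
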