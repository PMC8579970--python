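sample_id	column_id	time_point	sample_type	section	treatment	temperature_c
colA_d000	colA	0	effluent	none	treated	30
colA_d002	colA	2	effluent	none	treated	30
colA_d004	colA	4	effluent	none	treated	30
colA_d006	colA	6	effluent	none	treated	30
colA_d008	colA	8	effluent	none	treated	30
colA_d010	colA	10	effluent	none	treated	30
colB_d000	colB	0	effluent	none	nontreated	30
colB_d002	colB	2	effluent	none	nontreated	30
colB_d004	colB	4	effluent	none	nontreated	30
colB_d006	colB	6	effluent	none	nontreated	30
colB_d008	colB	8	effluent	none	nontreated	30
colB_d010	colB	10	effluent	none	nontreated	30
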