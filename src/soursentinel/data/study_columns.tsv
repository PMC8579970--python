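column_id	n_samples_total	n_samples_effluent	sacrifice_stage	treatment	temperature_c	harvest_batch
column01	47	44	rebound	treated	30	4
column02	47	44	sulfidogenesis	nontreated	30	4
column03	38	35	mitigation	treated	30	3
column04	27	24	mitigation	treated	30	2
column05	27	24	sulfidogenesis	nontreated	30	2
column06	25	22	mitigation	treated	30	1
column07	25	22	sulfidogenesis	nontreated	19	1
column08	25	22	sulfidogenesis	nontreated	30	1
column09	25	22	sulfidogenesis	nontreated	19	1
column10	25	22	mitigation	treated	19	1
column11	38	35	sulfidogenesis	nontreated	30	3
column12	47	44	sulfidogenesis	nontreated	30	4
column13	38	35	mitigation	treated	30	3
column14	27	24	mitigation	treated	19	2
column15	47	44	rebound	treated	30	4
column16	47	44	sulfidogenesis	nontreated	30	4
column17	38	35	sulfidogenesis	nontreated	30	3
column18	47	44	rebound	treated	30	4
column19	47	44	rebound	treated	30	4
column20	44	44	none	nontreated	30	0
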