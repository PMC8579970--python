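sample_id	asv_srb1	asv_srb2	asv_nrb	asv_bg
colA_d000	10	5	2	83
colA_d002	12	6	3	79
colA_d004	15	8	3	74
colA_d006	60	30	5	105
colA_d008	5	2	40	53
colA_d010	4	2	45	49
colB_d000	20	10	2	68
colB_d002	18	9	3	70
colB_d004	22	11	2	65
colB_d006	19	10	3	68
colB_d008	21	10	2	67
colB_d010	20	9	3	68
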