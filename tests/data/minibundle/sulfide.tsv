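column_id	time_point	sulfide_mm
colA	0	0.3
colA	2	1.8
colA	4	2.1
colA	6	1.4
colA	8	0.7
colA	10	0.4
colB	0	0.2
colB	2	0.9
colB	4	1.6
colB	6	2.1
colB	8	2.4
colB	10	2.5
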