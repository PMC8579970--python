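column_id	time_point	cells_per_ml	outlier
colA	0	9.5e6	False
colA	2	1.1e7	False
colA	4	1.2e7	False
colA	6	1.5e7	False
colA	8	8.0e6	False
colA	10	7.5e6	False
colB	0	1.0e7	False
colB	2	1.0e7	False
colB	4	1.1e7	False
colB	6	1.2e7	False
colB	8	1.1e7	False
colB	10	1.0e7	False
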