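column_id	nitrate_start	nitrate_stop	nitrate_mm
colA	4	10	3.3
colB			
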