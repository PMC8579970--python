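taxon_id	genome_label	is_srb	copy_number	has_dsr
asv_srb1	Desulfobacula toluolica Tol2	True	2	True
asv_srb2	Desulfobacula toluolica Tol2	True	4	True
asv_nrb	Thauera sp. MINI-N01	False	3	False
asv_bg	Bacterium sp. MINI-B01	False	1	False
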