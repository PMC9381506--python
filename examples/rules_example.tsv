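gene	ref_seq_id	ref_position	allowed	role
pepM	pepM_anchor_synthetic	58	DE	catalytic
pepM	pepM_anchor_synthetic	121	H	cofactor
pepM	pepM_anchor_synthetic	190	KR	substrate
phnX	phnX_anchor_synthetic	12	D	catalytic
phnX	phnX_anchor_synthetic	186	K	substrate
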