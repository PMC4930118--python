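comparison	family	up	down	genes_up	genes_down
LFQ	global	194	108
LFQ	initiation_factor	9	0	EIF1,EIF2S3,EIF3A,EIF3C,EIF3F,EIF4A,EIF4A3,EIF5A,EIF6
LFQ	elongation_factor	2	0	EEF1A1,EEF2
LFQ	ribosomal	22	1	RPL3,RPL7,RPL7A,RPL10,RPL10A,RPL12,RPL21,RPL22,RPL23,RPL27,RPL30,RPL36,RPLP0,RPLP2,RPS3,RPS8,RPS11,RPS12,RPS17L,RPS25,RPS26,RPSA	PRPS1
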