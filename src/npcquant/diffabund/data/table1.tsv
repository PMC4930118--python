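comparison	family	up	down	genes_up	genes_down
P1AxC1	global	2289	752
P1AxC1	initiation_factor	38	0	EIF2AK2,EIF2AK4,EIF2B1,EIF2B2,EIF2B3,EIF2S2,EIF3S3,EIF3S5,EIF3S6,EIF3S7,EIF3S8,EIF3S9,EIF3S10,EIF3S12,EIF4A2,EIF4A3,EIF4AB,EIF4G1,EIF4G2,EIF4G3,EIF5,EIF5A,EIF5B
P1AxC1	ribosomal	66	0	RPL3,RPL4,RPL6,RPL7,RPL8,RPL9,RPL10A,RPL11,RPL12,RPL13,RPL14,RPL15,RPL17,RPL18,RPL18A,RPL21,RPL22L1,RPL23,RPL23A,RPL24,RPL27A,RPL32,RPL36A,RPL37A,RPL38,RPLP0,RPLP1,RPLP2,RPN,RPN2,RPS2,RPS3,RPS6,RPS7,RPS10,RPS11,RPS12,RPS13,RPS17,RPS19,RPS20,RPS21,RPS24,RPS25,RPS27
P1BxC1	global	2401	886
P1BxC1	initiation_factor	36	0	EIF2AK2,EIF2AK4,EIF2B1,EIF2B2,EIF2B3,EIF2S2,EIF2S3,EIF3S3,EIF3S4,EIF3S5,EIF3S6,EIF3S8,EIF3S9,EIF3S10,EIF3S12,EIF4A2,EIF4A3,EIF4B,EIF4G1,EIF4G2,EIF4G3,EIF5,EIF5A,EIF5B
P1BxC1	elongation_factor	7	0	EEF1A1,EEF1A2,EEF1B2,EEF1E1,EEF1G,EEF2
P1BxC1	ribosomal	48	1	RPL3,RPL4,RPL6,RPL7,RPL7A,RPL8,RPL9,RPL10A,RPL14,RPL15,RPL17,RPL18,RPL18A,RPL21,RPL22L1,RPL23,RPL26,RPL26L1,RPL27A,RPL32,RPL36A,RPL37A,RPL38,RPLP0,RPLP1,RPLP2,RPLP10,RPS2,RPS3,RPS6,RPS7,RPS10,RPS12,RPS13,RPS17,RPS19,RPS20,RPS21,RPS24,RPS25,RPS27	RPL22
P3xC3	global	1123	366
P3xC3	initiation_factor	10	4	EIF2B1,EIF2S2,EIF2S3,EIF3S2,EIF3S4,EIF3S5,EIF3S12,EIF4A3,EIF4E,EIF5,EIF5A	EIF2C1,EIF2C3,EIF2C12
P3xC3	elongation_factor	3	0	EEF1A1,EEF1A2,EEF1G
P3xC3	ribosomal	14	1	RPL3,RPL8,RPL9,RPL10A,RPL14,RPL15,RPL17,RPL23,RPL32,RPLP1,RPLP2,RPS2,RPS7,RPS17	RPL22L1
P3xC6	global	541	880
P3xC6	initiation_factor	3	4	EIF3S5,EIF4G1,EIF5A	EIF2A,EIF2C1,EIF2C3,ELAV
P3xC6	ribosomal	10	3	RPA3,RPL21,RPL23A,RPL23AP2,RPL8,RPLP2,RPS3A,RPS29	RPL11,RPL36,RPS12
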