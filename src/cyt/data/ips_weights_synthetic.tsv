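gene	factor	category	weight
HLA-A	HLA-A	MHC	1.0
HLA-B	HLA-B	MHC	1.0
HLA-C	HLA-C	MHC	1.0
HLA-E	HLA-E	MHC	1.0
HLA-F	HLA-F	MHC	1.0
HLA-DPA1	HLA-DPA1	MHC	1.0
HLA-DPB1	HLA-DPB1	MHC	1.0
TAP1	TAP1	MHC	1.0
TAP2	TAP2	MHC	1.0
B2M	B2M	MHC	1.0
PDCD1	PDCD1	CP	-1.0
CTLA4	CTLA4	CP	-1.0
CD274	CD274	CP	-1.0
PDCD1LG2	PDCD1LG2	CP	-1.0
LAG3	LAG3	CP	-1.0
TIGIT	TIGIT	CP	-1.0
CD27	CD27	CP	1.0
ICOS	ICOS	CP	1.0
TNFRSF9	TNFRSF9	CP	1.0
CD8A	Act_CD8	EC	1.0
CD8B	Act_CD8	EC	1.0
GZMH	Act_CD8	EC	1.0
CD4	Act_CD4	EC	1.0
IL2RB	Act_CD4	EC	1.0
EOMES	Tem_CD8	EC	1.0
KLRD1	Tem_CD8	EC	1.0
CCR7	Tem_CD4	EC	1.0
SELL	Tem_CD4	EC	1.0
FOXP3	Treg	SC	-1.0
CCR8	Treg	SC	-1.0
ITGAM	MDSC	SC	-1.0
ARG1	MDSC	SC	-1.0
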