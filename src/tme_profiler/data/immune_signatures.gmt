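IFNG	6-gene interferon-gamma anti-PD-1 response signature (Ayers et al.; editable default)	IFNG	STAT1	IDO1	CXCL9	CXCL10	HLA-DRA
TIS	18-gene expanded T cell-inflamed anti-PD-1 response signature (Ayers et al.; editable default)	CCL5	CD27	CD274	CD276	CD8A	CMKLR1	CXCL9	CXCR6	HLA-DQA1	HLA-DRB1	HLA-E	IDO1	LAG3	NKG7	PDCD1LG2	PSMB10	STAT1	TIGIT
DYSFUNCTION	T cell dysfunction / exhaustion markers	HAVCR2	LAG3	PDCD1
STING	cGAS-STING pathway regulators	TMEM173	CGAS	CCL5	CXCL10	IRF3
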