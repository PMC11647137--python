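# alias	canonical HGNC symbol
PDL1	CD274
PD-L1	CD274
B7-H1	CD274
PDL2	PDCD1LG2
PD-L2	PDCD1LG2
PD1	PDCD1
PD-1	PDCD1
TIM3	HAVCR2
TIM-3	HAVCR2
VISTA	VSIR
B7H3	CD276
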