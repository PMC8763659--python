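pEMT_common	common partial-EMT program, 15 genes	ITGA5	LAMC2	LAMB3	LAMA3	MMP10	PDPN	TGFB1	VIM	EMP3	INHBA	P4HA2	TNC	CDH13	SEMA3C	TGFBI
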