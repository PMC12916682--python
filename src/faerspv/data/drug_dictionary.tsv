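DENOSUMAB	PROLIA
DENOSUMAB	XGEVA
DENOSUMAB	DENOSUMAB
ROMOSOZUMAB	EVENITY
ROMOSOZUMAB	ROMOSOZUMAB
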