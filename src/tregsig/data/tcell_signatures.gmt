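cytotoxicity	na	NKG7	CCL4	PRF1	GZMA	GZMB	IFNG	CCL3
exhaustion	na	PDCD1	TIGIT	LAG3	HAVCR2	CTLA4
naive	na	CCR7	TCF7	LEF1	SELL
effector_memory	na	CD27	CD28	CCR7	CCR5	SELL	FAS
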