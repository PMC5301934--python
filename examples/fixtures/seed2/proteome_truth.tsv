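kind	id	feature	start	end	truncated
domain	SYN0001_T01	domain	89	104	true
domain	SYN0002_T01	domain	2	43	false
domain	SYN0003_T01	domain	50	91	false
domain	SYN0004_T01	domain	22	63	false
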