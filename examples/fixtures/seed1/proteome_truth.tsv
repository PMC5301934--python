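kind	id	feature	start	end	truncated
domain	SYN0001_T01	domain	122	137	true
domain	SYN0002_T01	domain	32	73	false
domain	SYN0003_T01	domain	82	123	false
domain	SYN0004_T01	domain	265	306	false
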