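kind	id	feature	start	end	truncated
divergent_column	.	column	4	4	.
divergent_column	.	column	82	82	.
divergent_column	.	column	99	99	.
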