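kind	id	feature	start	end	truncated
divergent_column	.	column	15	15	.
divergent_column	.	column	24	24	.
divergent_column	.	column	113	113	.
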