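kind	id	feature	start	end	truncated
divergent_column	.	column	107	107	.
divergent_column	.	column	127	127	.
divergent_column	.	column	132	132	.
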