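segment	gene
PT_S1	SLC5A2
PT_S1	SLC5A12
PT_S3	SLC7A13
PT_S3	SLC5A10
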