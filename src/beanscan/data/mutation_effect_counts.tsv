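# Published coding-region mutation counts by effect and sharing category:
# shared between MW and MD, private to MW, private to MD.
effect	shared	private_mw	private_md
synonymous	42	40	3
nonsynonymous	27	23	5
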