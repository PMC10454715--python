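symbol	inheritance	missense_z	benign_nonvus_missense	total_nonvus_missense	lof_mechanism
CELSR1	AD		33	33	
SERPINA6	AR	-0.662			
TYR	AR				true
USH2A	AR		196	529	true
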