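MAPK1	1	MKNK1
MKNK1	1	EIF4E
MAPK1	1	RPS6KA5
RPS6KA5	-1	EIF4EBP1
MAPK1	-1	EIF4EBP1
MTOR	-1	EIF4EBP1
EIF4EBP1	-1	EIF4E
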