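node1	node2	homology	coexpression	experimental	database	textmining	combined
EIF4E	MAPK1	0	0.062	0.127	0	0.438	0.5
EIF4E	EIF4EBP1	0	0	0.996	0.9	0.994	0.999
EIF4E	MTOR	0	0.062	0.369	0.9	0.993	0.999
EIF4E	MKNK1	0	0	0.637	0.9	0.833	0.993
EIF4E	RPS6KA5	0	0.063	0	0	0.406	0.419
EIF4EBP1	MTOR	0	0	0.982	0.9	0.913	0.999
EIF4EBP1	RPS6KA5	0	0.049	0.213	0.9	0.578	0.964
EIF4EBP1	MAPK1	0	0	0.485	0.8	0.438	0.937
EIF4EBP1	MKNK1	0	0.055	0	0	0.556	0.563
MAPK1	MKNK1	0.582	0.056	0.721	0.9	0.787	0.98
MAPK1	RPS6KA5	0.642	0.062	0.319	0.9	0.388	0.939
MAPK1	MTOR	0	0.062	0.284	0	0.588	0.699
MKNK1	MTOR	0	0.062	0	0	0.391	0.404
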