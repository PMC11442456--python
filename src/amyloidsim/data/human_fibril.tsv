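# Human lysozyme irreversible fibril fold: twelve in-register inter-molecular
# beta-sheets (beta1-beta11 plus one 7-residue strand of unknown sequence).
# Unknown-density strands carry placeholder numbering >= 901 and the label
# "unassigned"; only their residue counts are meaningful.
# Columns: start	end	kind	label
23	32	strand	beta1
51	58	strand	beta2
62	63	strand	beta3
68	69	strand	beta4
74	75	strand	beta5
78	79	strand	beta6
83	87	strand	beta7
96	101	strand	beta8
107	112	strand	beta9
115	119	strand	beta10
120	125	strand	beta11
901	907	strand	unassigned
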