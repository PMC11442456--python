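# HEWL irreversible fibril fold: 11 in-register inter-molecular beta-sheets
# (beta1-beta9 plus strands of 6 and 4 residues of unknown sequence).
# Unknown-density strands carry placeholder numbering >= 901 and the label
# "unassigned"; only their residue counts are meaningful.
# Columns: start	end	kind	label
28	30	strand	beta1
33	38	strand	beta2
43	45	strand	beta3
51	52	strand	beta4
55	62	strand	beta5
73	76	strand	beta6
80	83	strand	beta7
89	92	strand	beta8
93	98	strand	beta9
901	906	strand	unassigned_a
911	914	strand	unassigned_b
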