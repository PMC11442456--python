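# Native human lysozyme fold (mature numbering, 130 residues).
# Sub-domain A: residues 1-40 and 86-130 (helical); sub-domain B: 41-85 (beta).
# Columns: start	end	kind	label
5	14	helix	A1
25	36	helix	A2
90	100	helix	A3
110	115	helix	A4
20	22	three10	G1
81	85	three10	G2
105	108	three10	G3
122	125	three10	G4
43	46	strand	b1
51	56	strand	b2
59	60	strand	b3
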