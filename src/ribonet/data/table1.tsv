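plastid_gene	plastid_residue	plastid_E1	plastid_W1	plastid_W2	plastid_W3	nuclear_gene	nuclear_residue	nuclear_E1	nuclear_W1	nuclear_W2	nuclear_W3	distance	before	after	after_raw
rpl32	Arg49	L	L	P	L	rpl17	Tyr122	-	-	-	-	4.37	h_bond	none	none
rpl14	Arg104	G	-	-	-	rpl19	Val155	-	-	-	-	4.17	none	none	none
rpl14	Arg104	G	-	-	-	rpl19	Glu157	-	-	-	-	4.85	none	none	none
rpl14	Arg104	G	-	-	-	rpl19	Ser163	-	-	-	-	2.98	polar	none	none
rpl14	Arg104	G	-	-	-	rpl19	Tyr165	-	-	-	-	2.99	polar	none	none
rps3	Lys146	-	-	-	-	rps5	Val198	-	-	-	I	3.86	none	none	none
rps11	Pro98	-	S	S	-	rps21	Ile113	-	-	-	-	3.47	none	none	none
rps11	Leu116	-	-	-	V	rps21	Cys116	-	-	-	-	3.86	none	none	none
rps11	Leu116	-	-	-	V	rps21	Val90	-	-	-	-	3.34	none	hydrophobic	hydrophobic
rps11	Ser117	-	-	-	-	rps21	Glu94	-	-	-	-	3.76	none	none	none
rps11	Ser117	-	-	-	-	rps21	Leu99	-	-	-	-	3.53	hydrophobic	hydrophobic	hydrophobic
rps11	Phe118	-	-	-	-	rps21	Val88	I	-	-	-	4.57	polar	polar	polar
rps11	Phe118	-	-	-	-	rps21	Leu89	F	-	-	S	3.41	none	none	none
rps11	Phe118	-	-	-	-	rps21	Val88	I	-	-	-	3.73	none	hydrophobic	hydrophobic
rps11	Phe118	-	-	-	-	rps21	Leu89	F	-	-	S	3.44	hydrophobic	none	hydrophobic/none
rps11	Val119	-	-	-	-	rps21	Val88	I	-	-	-	3.03	polar	polar	polar
rps11	Pro132	-	-	-	-	rps21	Tyr121	H	H	-	H	3.67	none	none	none
rps11	Pro133	-	-	-	-	rps21	Tyr121	H	H	-	H	3.49	none	none	none
rps11	Lys134	-	-	-	-	rps21	Tyr121	H	H	-	H	3.51	none	polar	polar
rps11	Lys135	-	-	-	-	rps21	Tyr121	H	H	-	H	3.79	none	h_bond	h_bond
rps11	Lys135	-	-	-	-	rps21	Glu127	-	D	D	D	3.12	salt_bridge	salt_bridge	salt_bridge
rps11	Arg136	-	-	-	-	rps21	Tyr121	H	H	-	H	3.3	h_bond	h_bond	h_bond
rps19	Arg65	-	-	Y	D	rps13	Arg124	-	-	-	-	2.64	h_bond	h_bond	h_bond
rps19	Arg65	-	-	Y	D	rps13	Glu127	-	-	-	Q	2.75	salt_bridge	none	none/none
rps19	Arg65	-	-	Y	D	rps13	Ile128	-	-	-	-	4.5	h_bond	none	none
rps18	Arg50	-	-	Q	-	rps21	Arg139	-	-	-	-	3.6	h_bond	none	none
rps18	Arg50	-	-	Q	-	rps21	Asn140	-	-	-	-	4.12	h_bond	h_bond	h_bond
rps18	Arg50	-	-	Q	-	rps21	Arg143	-	-	-	-	3.36	h_bond	none	none
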