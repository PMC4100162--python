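residue	any	backbone	sidechain	polar	hydrophobic	hbond_acceptor	hbond_donor	aromatic	charged
Q143	1	0.1	1	0.97	0	0	0.71	0	0
W308	1	0.68	1	1	0	0	0.71	1	0
H285	0.97	0.65	0.97	0.97	0	0	0.1	0	0
M194	0.94	0	0.94	0	0.94	0	0	0	0
L283	0.94	0.71	0.94	0.74	0.19	0	0	0	0
G144	0.9	0.9	0	0.35	0.55	0	0	0	0
R268	0.9	0.9	0.97	0.87	0.1	0.19	0	0	0.71
A286	0.86	0.86	0.86	0.23	0	0	0	0	0
L193	0.74	0.71	0.74	0.23	0.52	0	0	0	0
G147	0.72	0.72	0	0.59	0.13	0	0	0	0
S311	0.68	0.55	0.68	0.55	0.19	0.1	0	0	0
D190	0.56	0.56	0.16	0.46	0.1	0.16	0	0	0
C189	0.56	0.56	0	0.1	0.46	0	0	0	0
G191	0.56	0.56	0	0.53	0	0	0	0	0
A286	0.56	0.56	0	0.56	0	0	0	0	0
C149	0.52	0.29	0.9	0.39	0.52	0	0.13	0	0
N284	0.45	0.45	0.19	0.42	0	0.1	0	0	0
D142	0.32	0	0.32	0.32	0	0.1	0	0	0
Y270	0.29	0.29	0	0.26	0	0.13	0	0	0
W150	0.26	0.26	0.26	0.19	0	0	0	0	0
G262	0.26	0.26	0	0.1	0.16	0	0	0	0
D271	0.23	0.23	0.23	0.1	0.16	0	0	0	0
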