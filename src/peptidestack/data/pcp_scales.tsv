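# Default physicochemical-property table: 11 per-residue scales averaged
# over the sequence by the PCP encoder. Literature values:
# hydrophobicity (Kyte-Doolittle), hydrophilicity (Hopp-Woods), side-chain
# mass (Da), residue volume (Zamyatnin, A^3), polarity (Grantham),
# polarizability (Charton), isoelectric point of the free amino acid,
# net charge index at pH 7, alpha-helix and beta-sheet propensities
# (Chou-Fasman), average flexibility (Bhaskaran-Ponnuswamy).
# Users may substitute any table with the same layout (residue x scale).
residue	hydrophobicity	hydrophilicity	side_chain_mass	volume	polarity	polarizability	isoelectric_point	net_charge_index	helix_propensity	sheet_propensity	flexibility
A	1.8	-0.5	15.0	88.6	8.1	0.046	6.00	0.0	1.42	0.83	0.357
C	2.5	-1.0	47.0	108.5	5.5	0.128	5.07	0.0	0.70	1.19	0.346
D	-3.5	3.0	59.0	111.1	13.0	0.105	2.77	-1.0	1.01	0.54	0.511
E	-3.5	3.0	73.0	138.4	12.3	0.151	3.22	-1.0	1.51	0.37	0.497
F	2.8	-2.5	91.0	189.9	5.2	0.290	5.48	0.0	1.13	1.38	0.314
G	-0.4	0.0	1.0	60.1	9.0	0.000	5.97	0.0	0.57	0.75	0.544
H	-3.2	-0.5	82.0	153.2	10.4	0.230	7.59	0.1	1.00	0.87	0.323
I	4.5	-1.8	57.0	166.7	5.2	0.186	6.02	0.0	1.08	1.60	0.462
K	-3.9	3.0	73.0	168.6	11.3	0.219	9.74	1.0	1.16	0.74	0.466
L	3.8	-1.8	57.0	166.7	4.9	0.186	5.98	0.0	1.21	1.30	0.365
M	1.9	-1.3	75.0	162.9	5.7	0.221	5.74	0.0	1.45	1.05	0.295
N	-3.5	0.2	58.0	114.1	11.6	0.134	5.41	0.0	0.67	0.89	0.463
P	-1.6	0.0	42.0	112.7	8.0	0.131	6.30	0.0	0.57	0.55	0.509
Q	-3.5	0.2	72.0	143.8	10.5	0.180	5.65	0.0	1.11	1.10	0.493
R	-4.5	3.0	101.0	173.4	10.5	0.291	10.76	1.0	0.98	0.93	0.529
S	-0.8	0.3	31.0	89.0	9.2	0.062	5.68	0.0	0.77	0.75	0.507
T	-0.7	-0.4	45.0	116.1	8.6	0.108	5.60	0.0	0.83	1.19	0.444
V	4.2	-1.5	43.0	140.0	5.9	0.140	5.96	0.0	1.06	1.70	0.386
W	-0.9	-3.4	130.0	227.8	5.4	0.409	5.89	0.0	1.08	1.37	0.305
Y	-1.3	-2.3	107.0	193.6	6.2	0.298	5.66	0.0	0.69	1.47	0.420
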