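# aa_properties v1 — amino acid x physicochemical scale table
# provenance:
#   kf1..kf10   Kidera et al. (1985) J Protein Chem 4:23, ten orthogonal factors
#               (kf4 = hydrophobicity on an inverted scale)
#   strength    Fauchere & Pliska (1983) octanol side-chain transfer scale;
#               proxies pairwise-interaction strength (aromatic/hydrophobic high)
#   mjenergy    Eisenberg et al. (1984) consensus hydrophobicity; proxies
#               contact-energy-derived residue stickiness
#   core        Janin (1979) buried/accessible transfer scale (interface-core propensity)
#   rim         Zimmerman et al. (1968) polarity (interface-rim propensity)
#   surface     Hopp & Woods (1981) hydrophilicity (unchanged-accessibility propensity)
#   alpha/beta/turn  Chou & Fasman (1978) secondary-structure propensities
#   disorder    Campen et al. (2008) TOP-IDP intrinsic-disorder propensity
#   volume      Zamyatnin (1972) residue volume, A^3 (bulky residues W,Y,F,R,K rank highest)
#   polarity    Grantham (1974) polarity
#   charge      net side-chain charge at pH 7 (H = +0.1)
#   hydropathy  Kyte & Doolittle (1982)
aa	kf1	kf2	kf3	kf4	kf5	kf6	kf7	kf8	kf9	kf10	strength	mjenergy	core	rim	surface	alpha	beta	turn	disorder	volume	polarity	charge	hydropathy
A	-1.56	-1.67	-0.97	-0.27	-0.93	-0.78	-0.20	-0.08	0.21	-0.48	0.31	0.62	0.3	0.00	-0.5	1.42	0.83	0.66	0.060	88.6	8.1	0	1.8
R	0.22	1.27	1.37	1.87	-1.70	0.46	0.92	-0.39	0.23	0.93	-1.01	-2.53	-1.4	52.00	3.0	0.98	0.93	0.95	0.180	173.4	10.5	1	-4.5
N	1.14	-0.07	-0.12	0.81	0.18	0.37	-0.09	1.23	1.10	-1.73	-0.60	-0.78	-0.5	3.38	0.2	0.67	0.89	1.56	0.007	114.1	11.6	0	-3.5
D	0.58	-0.22	-1.58	0.81	-0.92	0.15	-1.52	0.47	0.76	0.70	-0.77	-0.90	-0.6	49.70	3.0	1.01	0.54	1.46	0.192	111.1	13.0	-1	-3.5
C	0.12	-0.89	0.45	-1.05	-0.71	2.41	1.52	-0.69	1.13	1.10	1.54	0.29	0.9	1.48	-1.0	0.70	1.19	1.19	0.020	108.5	5.5	0	2.5
Q	-0.47	0.24	0.07	1.10	1.10	0.59	0.84	-0.71	-0.03	-2.33	-0.22	-0.85	-0.7	3.53	0.2	1.11	1.10	0.98	0.318	143.8	10.5	0	-3.5
E	-1.45	0.19	-1.61	1.17	-1.31	0.40	0.04	0.38	-0.35	-0.12	-0.64	-0.74	-0.7	49.90	3.0	1.51	0.37	0.74	0.736	138.4	12.3	-1	-3.5
G	1.46	-1.96	-0.23	-0.16	0.10	-0.11	1.32	2.36	-1.66	0.46	0.00	0.48	0.3	0.00	0.0	0.57	0.75	1.56	0.166	60.1	9.0	0	-0.4
H	-0.41	0.52	-0.28	0.28	1.61	1.01	-1.85	0.47	1.13	1.63	0.13	-0.40	-0.1	51.60	-0.5	1.00	0.87	0.95	0.303	153.2	10.4	0.1	-3.2
I	-0.73	-0.16	1.79	-0.77	-0.54	0.03	-0.83	0.51	0.66	-1.78	1.80	1.38	0.7	0.13	-1.8	1.08	1.60	0.47	-0.486	166.7	5.2	0	4.5
L	-1.04	0.00	-0.24	-1.10	-0.55	-2.05	0.96	-0.76	0.45	0.93	1.70	1.06	0.5	0.13	-1.8	1.21	1.30	0.59	-0.326	166.7	4.9	0	3.8
K	-0.34	0.82	-0.23	1.70	1.54	-1.62	1.15	-0.08	-0.48	0.60	-0.99	-1.50	-1.8	49.50	3.0	1.16	0.74	1.01	0.586	168.6	11.3	1	-3.9
M	-1.40	0.18	-0.42	-0.73	2.00	1.52	0.26	0.11	-1.27	0.27	1.23	0.64	0.4	1.43	-1.3	1.45	1.05	0.60	-0.397	162.9	5.7	0	1.9
F	-0.21	0.98	-0.36	-1.43	0.22	-0.81	0.67	1.10	1.71	-0.44	1.79	1.19	0.5	0.35	-2.5	1.13	1.38	0.60	-0.697	189.9	5.2	0	2.8
P	2.06	-0.33	-1.15	-0.75	0.88	-0.45	0.30	-2.30	0.74	-0.28	0.72	0.12	-0.3	1.58	0.0	0.57	0.55	1.52	0.987	112.7	8.0	0	-1.6
S	0.81	-1.08	0.16	0.42	-0.21	-0.43	-1.89	-1.15	-0.97	-0.23	-0.04	-0.18	-0.1	1.67	0.3	0.77	0.75	1.43	0.341	89.0	9.2	0	-0.8
T	0.26	-0.70	1.21	0.63	-0.10	0.21	0.24	-1.15	-0.56	0.19	0.26	-0.05	-0.2	1.66	-0.4	0.83	1.19	0.96	0.059	116.1	8.6	0	-0.7
W	0.30	2.10	-0.72	-1.57	-1.16	0.57	-0.48	-0.40	-2.30	-0.60	2.25	0.81	0.3	2.10	-3.4	1.08	1.37	0.96	-0.884	227.8	5.4	0	-0.9
Y	1.38	1.48	0.80	-0.56	0.00	-0.68	-0.31	1.03	-0.05	0.53	0.96	0.26	-0.4	1.61	-2.3	0.69	1.47	1.14	-0.510	193.6	6.2	0	-1.3
V	-0.74	-0.71	2.04	-0.40	0.50	-0.81	-1.07	0.06	-0.46	0.65	1.22	1.08	0.6	0.13	-1.5	1.06	1.70	0.50	-0.121	140.0	5.9	0	4.2
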