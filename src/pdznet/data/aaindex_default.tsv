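# Default amino-acid property table (10 physicochemical indices, raw values).
# Columns: hbond_donors (Fauchere-Charton-style donor counts), polarity and
# volume (Grantham 1974), bulkiness / hydrophobicity / isoelectric_point
# (Zimmerman 1968), positive_charge / negative_charge (formal charge
# indicators), eiip (Cosic electron-ion interaction potential), free_energy_water
# (Charton-style solution free energy). Values are z-scored per column at load.
aa	hbond_donors	polarity	volume	bulkiness	hydrophobicity	isoelectric_point	positive_charge	negative_charge	eiip	free_energy_water
A	0	8.1	31	11.50	0.83	6.00	0	0	0.0373	-0.368
R	4	10.5	124	14.28	0.83	10.76	1	0	0.0959	-1.030
N	2	11.6	56	12.82	0.09	5.41	0	0	0.0036	0.000
D	1	13.0	54	11.68	0.64	2.77	0	1	0.1263	2.060
C	1	5.5	55	13.46	1.48	5.05	0	0	0.0829	4.530
Q	2	10.5	85	14.45	0.00	5.65	0	0	0.0761	0.731
E	1	12.3	83	13.57	0.65	3.22	0	1	0.0058	1.770
G	0	9.0	3	3.40	0.10	5.97	0	0	0.0050	-0.525
H	1	10.4	96	13.69	1.10	7.59	1	0	0.0242	0.000
I	0	5.2	111	21.40	3.07	6.02	0	0	0.0000	0.791
L	0	4.9	111	21.40	2.52	5.98	0	0	0.0000	1.070
K	2	11.3	119	15.71	1.60	9.74	1	0	0.0371	0.000
M	0	5.7	105	16.25	1.40	5.74	0	0	0.0823	0.656
F	0	5.2	132	19.80	2.75	5.48	0	0	0.0946	1.060
P	0	8.0	32.5	17.43	2.70	6.30	0	0	0.0198	-2.240
S	1	9.2	32	9.47	0.14	5.68	0	0	0.0829	-0.524
T	1	8.6	61	15.77	0.54	5.66	0	0	0.0941	0.000
W	1	5.4	170	21.67	0.31	5.89	0	0	0.0548	1.600
Y	1	6.2	136	18.03	2.97	5.66	0	0	0.0516	4.910
V	0	5.9	84	21.57	1.79	5.96	0	0	0.0057	0.401
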