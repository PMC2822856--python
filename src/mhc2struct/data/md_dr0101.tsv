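#allele=DRB1*0101
#source=md
#description=Binding free energy contribution (kcal/mol, relative to alanine) of each amino acid at core positions 1-9, from MM-PBSA evaluation of MD snapshots of the 2G9H complex. Positive = favourable for binding.
aa	1	2	3	4	5	6	7	8	9
ALA	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
ARG	1.88	4.71	8.55	9.80	2.67	6.45	10.54	3.95	13.93
ASN	1.47	0.68	1.94	0.85	1.39	1.17	0.64	1.53	3.18
ASP	-14.60	-2.82	-8.95	-5.53	-2.69	-11.09	-9.06	-6.01	-15.69
CYS	2.90	3.47	2.11	1.90	1.05	2.62	3.41	0.98	4.60
GLU	-14.82	-1.89	-8.90	-1.14	-3.13	-11.84	-11.20	-4.60	-15.98
GLN	3.87	2.86	4.08	8.34	1.04	3.75	6.21	1.39	6.12
GLY	-0.86	-1.48	-0.52	-1.74	0.31	-0.81	-2.51	0.00	-1.66
HIS	5.38	1.00	2.31	5.50	1.82	2.86	5.62	1.05	3.72
ILE	4.88	2.38	4.09	2.84	1.84	3.79	3.30	1.11	4.31
LEU	6.59	2.25	3.55	5.22	0.24	2.44	5.43	1.22	6.98
LYS	-5.99	1.59	10.68	5.20	3.35	3.79	3.61	2.40	2.51
MET	8.22	4.41	7.42	8.29	0.02	6.32	5.69	1.45	9.45
PHE	12.14	2.16	6.12	6.45	2.60	3.37	6.19	1.37	8.66
PRO	0.60	-3.51	0.93	-2.79	2.32	0.01	1.98	-2.71	0.60
SER	-1.25	0.36	-0.05	-1.52	0.85	1.03	1.64	0.19	1.16
THR	0.57	1.23	-0.69	0.23	0.65	3.66	0.80	0.20	0.42
TRP	13.49	2.02	6.32	-5.37	3.42	5.03	10.29	1.43	7.35
TYR	12.20	2.06	5.44	3.37	3.20	4.02	7.05	1.22	12.80
VAL	4.48	1.42	0.95	2.15	0.58	2.81	2.46	0.42	2.67
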