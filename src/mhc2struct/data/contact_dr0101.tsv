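#allele=DRB1*0101
#source=contact
#r=0.05
#description=Contact-map PSSM (natural-log units) for DRB1*0101, derived from atomic contacts (hydrogen bonds, van der Waals, hydrophobic) in six crystal complexes. Unobserved cells equal ln(0.05) = -3.00.
aa	1	2	3	4	5	6	7	8	9
ALA	-3.00	-3.00	-3.00	-3.00	0.99	1.50	1.33	-3.00	-3.00
ARG	-3.00	1.81	-3.00	-3.00	2.07	-3.00	-3.00	-3.00	-3.00
ASN	-3.00	-3.00	-3.00	-3.00	1.24	-3.00	-3.00	-3.00	-3.00
ASP	-3.00	-3.00	0.92	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00
CYS	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00
GLU	-3.00	-3.00	-3.00	0.85	-3.00	-3.00	-3.00	-3.00	-3.00
GLN	-3.00	-3.00	-3.00	1.72	0.77	-3.00	-3.00	-3.00	1.23
GLY	-3.00	0.89	0.29	-3.00	-3.00	1.02	-3.00	-3.00	0.32
HIS	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00	1.17	-3.00
ILE	0.79	1.24	1.38	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00
LEU	-3.00	-3.00	-3.00	2.10	-3.00	-3.00	1.27	2.25	2.36
LYS	-3.00	0.66	1.19	-3.00	-3.00	-3.00	-3.00	2.01	-3.00
MET	-3.00	-3.00	-3.00	1.41	-3.00	-3.00	-3.00	-3.00	-3.00
PHE	1.22	-3.00	1.82	-3.00	1.39	-3.00	-3.00	-3.00	-3.00
PRO	-3.00	-3.00	1.10	-3.00	-3.00	-3.00	1.85	-3.00	-3.00
SER	-3.00	0.89	-3.00	-3.00	-3.00	1.43	-3.00	-3.00	0.59
THR	-3.00	-3.00	-3.00	-3.00	-3.00	2.17	-3.00	-3.00	-3.00
TRP	1.53	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00
TYR	2.09	-3.00	-3.00	-3.00	-3.00	-3.00	1.87	-3.00	-3.00
VAL	0.65	1.37	-3.00	-3.00	-3.00	-3.00	-3.00	-3.00	1.12
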