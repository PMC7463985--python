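symbol	locus	role	fc_all	p_all	fc_filtered	p_filtered
GBE1	3p12.2	de_novo	-1.74	0.00	n.a.	n.a.
GYG1	3q24	de_novo	-1.15	0.01	n.a.	n.a.
GYG2	Xp22.33	de_novo	-2.30	0.00	-2.46	0.00
ATG7	3p25.3	positive	-1.32	0.00	n.a.	n.a.
BAP1	3p21.1	positive	-5.66	0.00	n.a.	n.a.
EPM2A	6q24.3	positive	-1.62	0.00	-1.74	0.00
INSR	19p13.2	positive	-1.32	0.00	-1.32	0.00
IRS2	13q34	positive	-1.41	0.00	-1.32	0.00
IRS4	Xq22.3	positive	-9.85	0.00	-8.57	0.02
PPP1R3B	8p23.1	positive	-2.83	0.00	-2.30	0.00
PPP1R3C	10q23.32	positive	-3.73	0.00	-3.73	0.00
CALM1	14q32.11	negative	1.41	0.00	1.41	0.00
CALM2	2p21	negative	1.52	0.00	1.52	0.00
G6PC3	17q21.31	negative	1.62	0.00	1.74	0.02
GFPT1	2p13.3	negative	1.74	0.00	1.74	0.00
GSK3B	3q13.33	negative	-1.23	0.00	n.a.	n.a.
PCK1	20q13.31	negative	5.66	0.00	6.96	0.00
PHKA2	Xp22.13	negative	-1.52	0.00	-1.52	0.03
PPP1R14C	6q25.1	negative	25.99	0.00	27.86	0.00
PYGM	11q13.1	negative	3.03	0.00	3.25	0.00
PGM2	4p14	dual	1.62	0.00	1.52	0.02
PGM5	9q21.11	dual	2.00	0.02	2.14	0.00
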