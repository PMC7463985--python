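symbol	locus	chrom	role	published
GBE1	3p12.2	3	de_novo	1
GYG1	3q24	3	de_novo	1
GYG2	Xp22.33	X	de_novo	1
ATG7	3p25.3	3	positive	1
BAP1	3p21.1	3	positive	1
EPM2A	6q24.3	6	positive	1
INSR	19p13.2	19	positive	1
IRS2	13q34	13	positive	1
IRS4	Xq22.3	X	positive	1
PPP1R3B	8p23.1	8	positive	1
PPP1R3C	10q23.32	10	positive	1
CALM1	14q32.11	14	negative	1
CALM2	2p21	2	negative	1
G6PC3	17q21.31	17	negative	1
GFPT1	2p13.3	2	negative	1
GSK3B	3q13.33	3	negative	1
PCK1	20q13.31	20	negative	1
PHKA2	Xp22.13	X	negative	1
PPP1R14C	6q25.1	6	negative	1
PYGM	11q13.1	11	negative	1
PGM2	4p14	4	dual	1
PGM5	9q21.11	9	dual	1
GAA	17q25.3	17	negative	1
GYS1	19q13.33	19	de_novo	0
GYS2	12p12.1	12	de_novo	0
UGP2	2p15	2	de_novo	0
PGM1	1p31.3	1	dual	0
PGM2L1	11q13.4	11	positive	0
PGM3	6q14.1	6	dual	0
AGL	1p21.2	1	negative	0
PYGB	20p11.21	20	negative	0
PYGL	14q22.1	14	negative	0
PHKA1	Xq13.1	X	negative	0
PHKB	16q12.1	16	negative	0
PHKG1	7p11.2	7	negative	0
PHKG2	16p11.2	16	negative	0
CALM3	19q13.32	19	negative	0
NHLRC1	6p22.3	6	positive	0
EPM2AIP1	3p22.1	3	positive	0
PPP1R2	3q29	3	negative	0
PPP1R3A	7q31.1	7	positive	0
PPP1R3D	20q13.33	20	positive	0
PPP1R3E	14q11.2	14	positive	0
PPP1R3F	Xp11.23	X	positive	0
PPP1R3G	6p21.31	6	positive	0
PPP1CA	11q13.2	11	positive	0
PPP1CB	2p23.2	2	positive	0
PPP1CC	12q24.11	12	positive	0
GSK3A	19q13.2	19	negative	0
IRS1	2q36.3	2	positive	0
AKT1	14q32.33	14	positive	0
AKT2	19q13.2	19	positive	0
PRKAA1	5p13.1	5	negative	0
PRKAA2	1p32.2	1	negative	0
PRKAB1	12q24.23	12	negative	0
PRKAB2	1q21.1	1	negative	0
PRKAG1	12q13.12	12	negative	0
PRKAG2	7q36.1	7	negative	0
PRKAG3	2q35	2	negative	0
G6PC1	17q21.31	17	negative	0
G6PC2	2q31.1	2	negative	0
SLC37A4	11q23.3	11	negative	0
STBD1	4q24	4	positive	0
GABARAPL1	12p13.31	12	positive	0
MGAM	7q34	7	negative	0
GANC	15q15.2	15	negative	0
AMY2A	1p21.1	1	negative	0
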