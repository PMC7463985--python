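variable	level	n_high	n_low
gender	Female	6	8
gender	Male	9	7
eye	Right	5	8
eye	Left	10	7
irradiation	No	8	7
irradiation	Yes	7	8
monosomy3_primary	No	12	4
monosomy3_primary	Yes	3	11
bap1_cytoplasmic	High	11	7
bap1_cytoplasmic	Low	4	8
bap1_nuclear	High	9	2
bap1_nuclear	Low	6	13
cmc_presence	No	1	1
cmc_presence	Yes	13	14
cmc_monosomy3	No	5	3
cmc_monosomy3	Yes	9	10
metastases	No	13	7
metastases	Yes	2	8
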