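# Circadian clock and clock-associated genes of Arabidopsis and their barley homologues.
# relation: one_to_one_orthologue | orthologue_ambiguous | paralogue | absent
#   (orthologue_ambiguous = one-to-one orthologue/paralogue assignment not determined)
# partial: 1 = identifier represents a partial gene sequence
# core_clock: 1 = family belongs to the ten-component ancestral core set
# source: table1 = printed catalogue table; text = named only in the running text
family	species	gene_name	identifier	relation	partial	core_clock	source
LHY	arabidopsis	AtCCA1	At2g46830	paralogue	0	1	table1
LHY	arabidopsis	AtLHY	At1g01060	one_to_one_orthologue	0	1	table1
LHY	barley	HvLHY	MLOC_14118	one_to_one_orthologue	0	1	table1
LHY	barley	CCA1		absent	0	1	text
LUX	arabidopsis	AtBOA	At5g59570	paralogue	0	1	table1
LUX	arabidopsis	AtLUX	At3g46640	one_to_one_orthologue	0	1	table1
LUX	barley	HvLUX	MLOC_37446	one_to_one_orthologue	0	1	table1
ELF3	arabidopsis	EEC		paralogue	0	1	table1
ELF3	arabidopsis	AtELF3	At2g25930	one_to_one_orthologue	0	1	table1
ELF3	barley	HvELF3	MLOC_78552	one_to_one_orthologue	1	1	table1
GI	arabidopsis	AtGI	At1g22770	one_to_one_orthologue	0	1	table1
GI	barley	HvGI	MLOC_70638	one_to_one_orthologue	1	1	table1
TOC1	arabidopsis	AtTOC1	At5g61380	one_to_one_orthologue	0	1	table1
TOC1	barley	HvTOC1	MLOC_52387	one_to_one_orthologue	0	1	table1
PRR9/5	arabidopsis	AtPRR5	At5g24470	orthologue_ambiguous	0	1	table1
PRR9/5	arabidopsis	AtPRR9	At2g46790	orthologue_ambiguous	0	1	table1
PRR9/5	barley	HvPRR95	MLOC_57021	orthologue_ambiguous	0	1	table1
PRR9/5	barley	HvPRR59	MLOC_62596	orthologue_ambiguous	1	1	table1
PRR3/7	arabidopsis	AtPRR3	At5g60100	paralogue	0	1	table1
PRR3/7	arabidopsis	AtPRR7	At5g02810	one_to_one_orthologue	0	1	table1
PRR3/7	barley	HvPpd-H1	MLOC_81154	one_to_one_orthologue	0	1	table1
PRR3/7	barley	HvPRR73	MLOC_12732	paralogue	0	1	table1
ZTL	arabidopsis	AtLPK2	At2g18915	paralogue	0	1	table1
ZTL	arabidopsis	AtZTL	At5g57360	one_to_one_orthologue	0	1	table1
ZTL	barley	HvZTLa	MLOC_44010	orthologue_ambiguous	0	1	table1
ZTL	barley	HvZTLb	MLOC_20007	orthologue_ambiguous	0	1	table1
FKF1	arabidopsis	AtFKF1	At1g68050	one_to_one_orthologue	0	1	table1
FKF1	barley	HvFKF1	MLOC_53725	one_to_one_orthologue	0	1	table1
GRP7	arabidopsis	AtGRP8	At4g39260	paralogue	0	0	table1
GRP7	arabidopsis	AtGRP7	At2g21660	one_to_one_orthologue	0	0	table1
GRP7	barley	HvGRP7a	MLOC_17819	orthologue_ambiguous	1	0	table1
GRP7	barley	HvGRP7b	MLOC_59695	orthologue_ambiguous	1	0	table1
CO	arabidopsis	AtCOL2	At3g02380	paralogue	0	0	table1
CO	arabidopsis	AtCO	At5g15840	orthologue_ambiguous	0	0	table1
CO	arabidopsis	AtCOL1	At5g15850	orthologue_ambiguous	0	0	table1
CO	barley	HvCO1	MLOC_6921	orthologue_ambiguous	1	0	table1
CO	barley	HvCO2	MLOC_75496	orthologue_ambiguous	1	0	table1
FT	arabidopsis	AtTSF	At4g20370	paralogue	0	0	table1
FT	arabidopsis	AtFT	At1g65480	one_to_one_orthologue	0	0	table1
FT	barley	HvFT1	MLOC_68576	orthologue_ambiguous	0	0	table1
FT	barley	HvFT2	MLOC_10172	orthologue_ambiguous	1	0	table1
ELF4	arabidopsis	AtELF4	At2g40080	paralogue	0	0	table1
ELF4	arabidopsis	AtELF4-like1	At2g29950	paralogue	0	0	table1
ELF4	barley	ELF4		absent	0	0	text
ELF4-like	arabidopsis	AtELF4-like4	At1g17455	paralogue	0	1	table1
ELF4-like	arabidopsis	AtELF4-like2	At1g72630	paralogue	0	1	table1
ELF4-like	arabidopsis	AtELF4-like3	At2g06255	one_to_one_orthologue	0	1	table1
ELF4-like	barley	HvELF4-like3	MLOC_70937	one_to_one_orthologue	0	1	table1
ELF4-like	barley	HvELF4-likeA	MLOC_58590	paralogue	0	1	table1
CHE	arabidopsis	AtCHE		one_to_one_orthologue	0	0	text
CHE	barley	CHE		absent	0	0	text
CAB	arabidopsis	AtCAB2		one_to_one_orthologue	0	0	text
CAB	barley	CAB2		absent	0	0	text
CAB	barley	HvCABa		paralogue	0	0	text
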