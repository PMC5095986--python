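symbol	chromosome	transcript	protein
BRAF	7	NM_004333.4	NP_004324.2
KRAS	12	NM_004985.5	NP_004976.2
NRAS	1	NM_002524.5	NP_002515.1
EGFR	7	NM_005228.5	NP_005219.2
TP53	17	NM_000546.6	NP_000537.3
PIK3CA	3	NM_006218.4	NP_006209.2
PTEN	10	NM_000314.8	NP_000305.3
ALK	2	NM_004304.5	NP_004295.2
KIT	4	NM_000222.3	NP_000213.1
PDGFRA	4	NM_006206.6	NP_006197.1
ERBB2	17	NM_004448.4	NP_004439.2
MET	7	NM_000245.4	NP_000236.2
RET	10	NM_020975.6	NP_066124.1
FLT3	13	NM_004119.3	NP_004110.2
IDH1	2	NM_005896.4	NP_005887.2
IDH2	15	NM_002168.4	NP_002159.2
JAK2	9	NM_004972.4	NP_004963.1
ABL1	9	NM_005157.6	NP_005148.2
NPM1	5	NM_002520.7	NP_002511.1
FGFR2	10	NM_000141.5	NP_000132.3
FGFR3	4	NM_000142.5	NP_000133.1
SMO	7	NM_005631.5	NP_005622.1
PTCH1	9	NM_000264.5	NP_000255.2
CDKN2A	9	NM_000077.5	NP_000068.1
RB1	13	NM_000321.3	NP_000312.2
APC	5	NM_000038.6	NP_000029.2
VHL	3	NM_000551.4	NP_000542.1
CTNNB1	3	NM_001904.4	NP_001895.1
AKT1	14	NM_005163.2	NP_005154.2
MAP2K1	15	NM_002755.4	NP_002746.1
ROS1	6	NM_002944.3	NP_002935.2
ESR1	6	NM_000125.4	NP_000116.2
AR	X	NM_000044.6	NP_000035.2
FBXW7	4	NM_033632.3	NP_361014.1
NF1	17	NM_000267.3	NP_000258.1
ATM	11	NM_000051.4	NP_000042.3
BRCA1	17	NM_007294.4	NP_009225.1
BRCA2	13	NM_000059.4	NP_000050.3
TERT	5	NM_198253.3	NP_937983.2
MYC	8	NM_002467.6	NP_002458.2
MTOR	1	NM_004958.4	NP_004949.1
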