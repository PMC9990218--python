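patient_id	gene_id	variant	chrom
A	TERT	TERT promoter	chr5
A	ERCC1	ERCC1	chr19
B	NF2	NF2:p.Phe94Ter	chr22
B	TERT	TERT promoter	chr5
B	SPTA1	SPTA1	chr1
B	NF1	NF1	chr17
C	NF2	NF2:p.Arg57Ter	chr22
C	POLE	POLE	chr12
D	SETD2	SETD2	chr3
D	NAB2-STAT6	NAB2-STAT6	chr12
D	PIK3C2B	PIK3C2B	chr1
D	DNMT3B	DNMT3B	chr20
D	ABRAXAS1	ABRAXAS1	chr4
D	IRF4	IRF4	chr6
E	NF2	NF2:p.Lys332SerfsTer14	chr22
E	CREBBP	CREBBP	chr16
E	MST1	MST1	chr3
E	PNRC1	PNRC1	chr6
F	TSC2	TSC2	chr16
G	NF2	NF2:p.Ala323ProfsTer23	chr22
G	NF2	NF2:p.Glu342Ter	chr22
G	NF2	NF2:p.Glu362ArgfsTer13	chr22
G	SF3B1	SF3B1	chr2
H	IFNGR1	IFNGR1	chr6
I	PTPN11	PTPN11	chr12
I	PIK3CA	PIK3CA	chr3
I	TRAF7	TRAF7	chr16
I	LATS2	LATS2	chr13
I	GEN1	GEN1	chr2
I	LRP1B	LRP1B	chr2
J	TP53	TP53	chr17
J	NAB2-STAT6	NAB2-STAT6	chr12
J	SPTA1	SPTA1	chr1
J	SLX4	SLX4	chr16
J	CDK12	CDK12	chr17
J	NKX3-1	NKX3-1	chr8
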