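gene	chrom
ABL1	chr9
AKT1	chr14
ALK	chr2
APC	chr5
ATM	chr11
BRAF	chr7
CDH1	chr16
CDKN2A	chr9
CSF1R	chr5
CTNNB1	chr3
EGFR	chr7
ERBB2	chr17
ERBB4	chr2
FBXW7	chr4
FGFR1	chr8
FGFR2	chr10
FGFR3	chr4
FLT3	chr13
GNA11	chr19
GNAQ	chr9
GNAS	chr20
HNF1A	chr12
HRAS	chr11
IDH1	chr2
JAK2	chr9
JAK3	chr19
KDR	chr4
KIT	chr4
KRAS	chr12
MET	chr7
MLH1	chr3
MPL	chr1
NOTCH1	chr9
NPM1	chr5
NRAS	chr1
PDGFRA	chr4
PIK3CA	chr3
PTEN	chr10
PTPN11	chr12
RB1	chr13
RET	chr10
SMAD4	chr18
SMARCB1	chr22
SMO	chr7
SRC	chr20
STK11	chr19
TP53	chr17
VHL	chr3
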