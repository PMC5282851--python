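gene	hgvs_p	patient	histology	af_percent	impact
HNF1A	p.Gly306fs	5	LUAD	15	Deleterious
TP53	p.Gly272fs	9	LUAD	15	Deleterious
TP53	p.Val173Met	10	LUAD	17	Deleterious
MLH1	p.Ser406Asn	12	LUAD	15	Deleterious
KIT	p.Glu76Asp	12	LUAD	50	Unknown
TP53	p.Leu206_Arg209del	12	LUAD	70	Unknown
ABL1	p.Thr243Ile	65	LUAD	15	Unknown
KRAS	p.Gly12Cys	65	LUAD	31	Activated
CTNNB1	p.Ser33Phe	89	LUAD	11	Activated
KRAS	p.Gly12Asp	90	LUAD	30	Activated
TP53	p.Cys238Tyr	91	LUSC	44	Deleterious
NOTCH1	p.Leu1600Pro	105	LUSC	11	Activated
TP53	p.Arg175fs	106	LUSC	56	Deleterious
HRAS	p.Gly13Val	120	LUSC	82	Activated
AKT1	p.Glu17Lys	120	LUSC	4	Activated
TP53	p.Ser215Gly	131	LUSC	45	Deleterious
ATM	p.Asn856Ile	140	LUSC	10	Unknown
TP53	p.His214Arg	150	LUSC	33	Deleterious
TP53	p.Arg337Pro	152	LUSC	50	Deleterious
VHL	p.Lys171Arg	161	NSCLC	18	Deleterious
TP53	p.Arg248Gln	161	NSCLC	31	Deleterious
TP53	p.Ser185fs	187	NSCLC	17	Deleterious
RB1	p.Ser576fs	187	NSCLC	18	Deleterious
PIK3CA	p.Glu545Lys	193	NSCLC	15	Activated
TP53	p.Tyr205Asp	193	NSCLC	22	Deleterious
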