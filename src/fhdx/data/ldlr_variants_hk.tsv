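cdna	protein_change	localization	n_probands	n_cascade	clinical_significance	novel	note
c.268 G>A	p.(Asp90Asn)	exon 3	1	0	Pathogenic	0
c.301 G>A	p.(Glu101Lys)	exon 3	1	0	Pathogenic	0
c.523 G>A	p.(Asp175Asn)	exon 4	1	0	Pathogenic	0
c.769 C>T	p.(Arg257Trp)	exon 5	1	0	VUS	0
c.837 dupC	p.(Asn280GlnfsTer21)	exon 6	1	0	Likely pathogenic	1
c.986 G>A	p.(Cys329Tyr)	exon 7	2	1	Likely pathogenic	0
c.1055 G>A	p.(Cys352Tyr)	exon 7	1	0	Pathogenic	0
c.1060+2 T>C		intron 7	1	0	Pathogenic	1	Splice donor variant
c.1216 C>A	p.(Arg406=)	exon 9	1	0	Likely pathogenic	0	New splice acceptor introduced
c.1241 T>G	p.(Leu414Arg)	exon 9	3	3	Likely pathogenic	0
c.1247 G>A	p.(Arg416Gln)	exon 9	1	1	Pathogenic	0
c.1285 G>A	p.(Val429Met)	exon 9	1	0	Pathogenic	0
c.1297 G>C	p.(Asp433His)	exon 9	1	0	Likely pathogenic	0
c.1448 G>A	p.(Trp483Ter)	exon 10	1	2	Pathogenic	0
c.1469 G>A	p.(Trp490Ter)	exon 10	1	0	Pathogenic	0
c.1586+5 G>C		intron 10	1	0	Likely pathogenic	0	Intron variant
c.1706-1 G>C		intron 11	1	0	Pathogenic	0	Splice acceptor variant
c.1731 G>C	p.(Trp577Cys)	exon 12	1	4	Pathogenic	0
c.1765 G>A	p.(Asp589Asn)	exon 12	1	1	VUS/Likely pathogenic	0
c.1880 C>T	p.(Ala627Val)	exon 13	1	1	Likely pathogenic	0
c.2001_2002 del	p.(Cys667*)	exon 13	1	0	Pathogenic	0
c.2026 G>A	p.(Gly676Ser)	exon 13	1	0	Likely pathogenic	0
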