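# Packaged 11-marker allele-specific PCR panel for soybean origin discrimination.
# Columns mirror the published panel definition: multiplex set, marker index,
# final primer concentration (ng/uL), primer sequences, amplicon size (bp).
set	marker	final_conc	forward	reverse	size
A	1	1.05	CCAATATCGATCTTTACCAATTCA	TAGCATATTAATCAAACATTTTCTAAA	102
B	3	0.09	TTGGACTGGAGCGTGGAGC	CACCCAAATGGTCATTAGCC	473
B	4	0.35	CAGAGCTTCAGTTCTTGACATCAG	TCAAAGAAACAAAACATAGGAAGATG	138
B	11	1.05	CGAAATTTTGAAATATACTTGAGAGGA	GCAGGTTCTCATGCAAAATG	112
C	2	0.18	TGAGTGGGTGTGTGTAATAAGTCTT	TGATGGGTTGGACGGTCTAT	238
C	5	1.05	CACCCACTCGTTTATCTCGTC	GCGTGTTTGGACTTGGATTG	107
D	6	1.05	TGTATTTGGGACAACTTATTACGTG	CGCACATTAAACACATGTGAAC	459
D	7	0.35	CCTTGGTCTTCCACTGCG	TTCGTATTGGGGGTTCAAAA	246
D	8	0.35	GGGCATGTCGTCAAGCTTGTC	CCACCTACCCGCAAAACGAT	112
E	9	0.18	TTCTTTCGAGTATTCCCTTTCG	TAGGTGCCTTACGAAAGTTATTATAA	324
F	10	0.35	GCGAATCCAAGACCTAAGTCAG	AAACCACTTGGGTGCCTTTA	872
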