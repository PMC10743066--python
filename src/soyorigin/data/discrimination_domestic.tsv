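# Domestic soybean discrimination table: 53 judgment values, 630 samples.
judgment_value	m1	m2	m3	m4	m5	m6	m7	m8	m9	m10	m11	duplicate_count	origin	note
25	1			8	16							9	domestic	
31	1	2	4	8	16							1	domestic	
55	1	2	4		16	32						6	domestic	
89	1			8	16		64					8	domestic	
151	1	2	4		16			128				14	domestic	
157	1		4	8	16			128				6	domestic	
189	1		4	8	16	32		128				12	domestic	Sinhwa
409	1			8	16			128	256			4	domestic	
425	1			8		32		128	256			1	domestic	
529	1				16					512		45	domestic	Taekwang
537	1			8	16					512		14	domestic	
659	1	2			16			128		512		5	domestic	
663	1	2	4		16			128		512		8	domestic	
665	1			8	16			128		512		10	domestic	Hwangkeumol/Seonyu
667	1	2		8	16			128		512		6	domestic	
669	1		4	8	16			128		512		8	domestic	
671	1	2	4	8	16			128		512		10	domestic	
785	1				16				256	512		4	domestic	
787	1	2			16				256	512		8	domestic	Cheongja-3
819	1	2			16	32			256	512		27	domestic	Cheonsang
827	1	2		8	16	32			256	512		16	domestic	Nampung
879	1	2	4	8		32	64		256	512		21	domestic	Daepung
937	1			8		32		128	256	512		11	domestic	
939	1	2		8		32		128	256	512		16	domestic	
1041	1				16						1024	5	domestic	
1045	1		4		16						1024	4	domestic	
1047	1	2	4		16						1024	7	domestic	
1049	1			8	16						1024	18	domestic	
1077	1		4		16	32					1024	4	domestic	
1079	1	2	4		16	32					1024	1	domestic	
1171	1	2			16			128			1024	6	domestic	
1175	1	2	4		16			128			1024	24	domestic	
1183	1	2	4	8	16			128			1024	8	domestic	
1203	1	2			16	32		128			1024	3	domestic	Cheongja1
1207	1	2	4		16	32		128			1024	8	domestic	
1215	1	2	4	8	16	32		128			1024	11	domestic	Pungsannamul
1339	1	2		8	16	32			256		1024	6	domestic	
1427	1	2			16			128	256		1024	4	domestic	
1431	1	2	4		16			128	256		1024	16	domestic	
1459	1	2			16	32		128	256		1024	2	domestic	
1467	1	2		8	16	32		128	256		1024	4	domestic	
1471	1	2	4	8	16	32		128	256		1024	74	domestic	
1563	1	2		8	16					512	1024	13	domestic	Uram
1567	1	2	4	8	16					512	1024	1	domestic	
1595	1	2		8	16	32				512	1024	6	domestic	
1677	1		4	8				128		512	1024	32	domestic	Saedanbaek
1681	1				16			128		512	1024	7	domestic	
1683	1	2			16			128		512	1024	1	domestic	
1687	1	2	4		16			128		512	1024	58	domestic	Daewon
1695	1	2	4	8	16			128		512	1024	6	domestic	
1719	1	2	4		16	32		128		512	1024	14	domestic	Hwangkeum
1909	1		4		16	32	64		256	512	1024	16	domestic	Pungwon
1939	1	2			16			128	256	512	1024	1	domestic	
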