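# Imported (foreign) soybean discrimination table: 70 judgment values, 466 samples.
judgment_value	m1	m2	m3	m4	m5	m6	m7	m8	m9	m10	m11	duplicate_count	origin	note
245	1		4		16	32	64	128				3	foreign	
247	1	2	4		16	32	64	128				11	foreign	
253	1		4	8	16	32	64	128				5	foreign	
429	1		4	8		32		128	256			2	foreign	
447	1	2	4	8	16	32		128	256			8	foreign	
493	1		4	8		32	64	128	256			6	foreign	
495	1	2	4	8		32	64	128	256			12	foreign	
541	1		4	8	16					512		2	foreign	
573	1		4	8	16	32				512		1	foreign	
601	1			8	16		64			512		3	foreign	
671	1	2	4	8	16			128		512		4	foreign	
701	1		4	8	16	32		128		512		1	foreign	
703	1	2	4	8	16	32		128		512		1	foreign	
733	1		4	8	16		64	128		512		2	foreign	
735	1	2	4	8	16		64	128		512		1	foreign	
743	1	2	4			32	64	128		512		4	foreign	
751	1	2	4	8		32	64	128		512		8	foreign	
757	1		4		16	32	64	128		512		1	foreign	
765	1		4	8	16	32	64	128		512		6	foreign	
767	1	2	4	8	16	32	64	128		512		4	foreign	
943	1	2	4	8		32		128	256	512		6	foreign	
1023	1	2	4	8	16	32	64	128	256	512		11	foreign	
1055	1	2	4	8	16						1024	8	foreign	
1059	1	2				32					1024	1	foreign	
1085	1		4	8	16	32					1024	12	foreign	
1165	1		4	8				128			1024	7	foreign	
1179	1	2		8	16			128			1024	21	foreign	
1181	1		4	8	16			128			1024	8	foreign	
1183	1	2	4	8	16			128			1024	6	foreign	
1197	1		4	8		32		128			1024	16	foreign	
1215	1	2	4	8	16	32		128			1024	9	foreign	
1229	1		4	8			64	128			1024	4	foreign	
1261	1		4	8		32	64	128			1024	10	foreign	
1263	1	2	4	8		32	64	128			1024	7	foreign	
1277	1		4	8	16	32	64	128			1024	5	foreign	
1279	1	2	4	8	16	32	64	128			1024	12	foreign	
1323	1	2		8		32			256		1024	2	foreign	
1343	1	2	4	8	16	32			256		1024	9	foreign	
1387	1	2		8		32	64		256		1024	14	foreign	
1407	1	2	4	8	16	32	64		256		1024	8	foreign	
1487	1	2	4	8			64	128	256		1024	18	foreign	
1535	1	2	4	8	16	32	64	128	256		1024	4	foreign	
1565	1		4	8	16					512	1024	14	foreign	
1575	1	2	4			32				512	1024	12	foreign	
1597	1		4	8	16	32				512	1024	5	foreign	
1599	1	2	4	8	16	32				512	1024	1	foreign	
1647	1	2	4	8		32	64			512	1024	4	foreign	
1691	1	2		8	16			128		512	1024	3	foreign	
1693	1		4	8	16			128		512	1024	8	foreign	
1695	1	2	4	8	16			128		512	1024	1	foreign	
1709	1		4	8		32		128		512	1024	4	foreign	
1711	1	2	4	8		32		128		512	1024	7	foreign	
1725	1		4	8	16	32		128		512	1024	10	foreign	
1727	1	2	4	8	16	32		128		512	1024	13	foreign	
1741	1		4	8			64	128		512	1024	8	foreign	
1757	1		4	8	16		64	128		512	1024	14	foreign	
1759	1	2	4	8	16		64	128		512	1024	13	foreign	
1773	1		4	8		32	64	128		512	1024	19	foreign	
1775	1	2	4	8		32	64	128		512	1024	2	foreign	
1791	1	2	4	8	16	32	64	128		512	1024	4	foreign	
1789	1		4	8	16	32	64	128		512	1024	1	foreign	
1951	1	2	4	8	16			128	256	512	1024	7	foreign	
1965	1		4	8		32		128	256	512	1024	8	foreign	
1967	1	2	4	8		32		128	256	512	1024	13	foreign	
1981	1		4	8	16	32		128	256	512	1024	4	foreign	
1983	1	2	4	8	16	32		128	256	512	1024	4	foreign	
2015	1	2	4	8	16		64	128	256	512	1024	2	foreign	
2031	1	2	4	8		32	64	128	256	512	1024	1	foreign	
2045	1		4	8	16	32	64	128	256	512	1024	1	foreign	
2047	1	2	4	8	16	32	64	128	256	512	1024	0	foreign	Williams82
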