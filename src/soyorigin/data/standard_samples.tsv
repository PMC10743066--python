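# Judgment values of the 16 standard varieties (15 Korean + Williams 82)
# genotyped with the packaged 11-marker panel.
variety	origin	m1	m2	m3	m4	m5	m6	m7	m8	m9	m10	m11	judgment_value
Daewon	domestic	1	2	4		16			128		512	1024	1687
Taekwang	domestic	1				16				256	512		785
Pungsannamul	domestic	1	2	4	8	16	32		128			1024	1215
Seonyu	domestic	1			8	16			128		512		665
Daepung	domestic	1	2	4	8		32	64			512		623
Sinhwa	domestic	1		4	8	16	32		128				189
Hwangkeum	domestic	1	2	4		16	32		128		512	1024	1719
Nampung	domestic	1	2		8	16	32			256	512		827
Cheonsang	domestic	1	2			16	32			256	512		819
Uram	domestic	1	2		8	16					512	1024	1563
Hwangkeumol	domestic	1			8	16			128		512		665
Saedanbaek	domestic	1		4	8				128		512	1024	1677
Pungwon	domestic	1		4		16	32	64		256	512	1024	1909
Cheongja1	domestic	1	2			16	32		128			1024	1203
Cheongja3	domestic	1	2			16				256	512		787
Williams82	imported	1	2	4	8	16	32	64	128	256	512	1024	2047
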