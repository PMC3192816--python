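id	label	anticodon	amino_acid	gene_copy_number
1	Ala1	AGC	A	11
2	Ala2	UGC	A	5
3	Arg1	ACG	R	6
4	Arg2	CCG	R	1
5	Arg3	CCU	R	1
6	Arg4	UCU	R	11
7	Asn1	GUU	N	10
8	Asp1	GUC	D	15
9	Cys1	GCA	C	4
10	Gln1	CUG	Q	1
11	Gln2	UUG	Q	9
12	Glu1	CUC	E	2
13	Glu2	UUC	E	14
14	Gly1	CCC	G	2
15	Gly2	GCC	G	16
16	Gly3	UCC	G	3
17	His1	GUG	H	7
18	Ile1	AAU	I	13
19	Ile2	UAU	I	2
20	Leu1	CAA	L	10
21	Leu2	GAG	L	3
22	Leu3	UAA	L	7
23	Leu4	UAG	L	2
24	Lys1	CUU	K	14
25	Lys2	UUU	K	7
26	Met1	CAU	M	5
27	Phe1	GAA	F	10
28	Pro1	AGG	P	2
29	Pro2	UGG	P	10
30	Ser1	AGA	S	11
31	Ser2	CGA	S	1
32	Ser3	GCU	S	4
33	Ser4	UGA	S	3
34	Thr1	AGU	T	11
35	Thr2	CGU	T	1
36	Thr3	UGU	T	4
37	Trp1	CCA	W	6
38	Tyr1	GUA	Y	8
39	Val1	AAC	V	14
40	Val2	CAC	V	2
41	Val3	UAC	V	2
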