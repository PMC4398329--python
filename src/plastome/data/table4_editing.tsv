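# RNA editing sites of the sweet potato plastome, transcribed as
# printed.  Intron rows carry the printed pseudo-codon context and
# its amino acids; the anomaly column flags the two printed
# irregularities (psbK amino acids, ycf3 label position).
gene	genome_pos	gene_pos	aa_pos	triplet_pos	dna_base	rna_base	codon_before	codon_after	aa_before	aa_after	region	label	anomaly
rps16	5007	976	326	1	C	U	CUA	UUA	L	L	exon	rps16eU976LL	.
rps16	5755	226	76	.	C	U	UGC	UGU	C	C	intron	rps16iU226CC	.
psbK	7440	136	46	1	C	U	CUC	UUC	S	L	exon	psbKeU136SL	printed_aa_change_inconsistent_with_codons
atpA	11006	914	305	2	C	U	UCA	UUA	S	L	exon	atpAeU914SL	.
atpF	13143	92	31	2	C	U	CCA	CUA	P	L	exon	atpFeU92PL	.
rps2	16508	134	45	2	C	U	ACA	AUA	T	I	exon	rps2eU134TI	.
rpoB	26998	338	113	2	C	U	UCU	UUU	S	F	exon	rpoBeU338SF	.
psbD	34240	53	18	2	C	U	ACU	AUU	T	I	exon	psbDeU53TI	.
rps14	38487	149	50	2	C	U	CCA	CUA	P	L	exon	rps14eU149PL	.
ycf3	44366	1668	556	.	C	U	GAC	GAU	D	D	intron	ycf3iU1168DD	label_position_1168_vs_printed_1668
ndhJ	50916	320	107	2	C	U	GCG	GUG	A	V	exon	ndhJeU320AV	.
ndhK	51549	683	228	2	U	C	AUG	ACG	M	T	exon	ndhKeC683MT	.
ndhK	51601	697	233	1	C	U	CUU	UUU	L	F	exon	ndhKeU697LF	.
ndhK	52001	231	77	3	U	C	AAU	AAC	N	N	exon	ndhKeC231NN	.
ndhC	52196	278	93	2	C	U	GCA	GUA	A	V	exon	ndhCeU278AV	.
accD	59371	232	78	1	C	U	CAU	UAU	H	Y	exon	accDeU232HY	.
accD	59681	551	184	2	C	U	ACU	AUU	T	I	exon	accDeU551TI	.
cemA	63358	242	81	2	C	U	CCA	CUA	P	L	exon	cemAeU242PL	.
petA	64560	527	176	2	C	U	GCU	GUU	A	V	exon	petAeU527AV	.
psbE	66431	214	72	1	C	U	CCU	UCU	P	S	exon	psbEeU214PS	.
rpl33	69762	20	7	2	C	U	GCA	GUA	A	V	exon	rpl33eU20AV	.
rps18	70166	33	11	3	C	U	UCC	UCU	S	S	exon	rps18eU33SS	.
rpl20	70956	131	44	2	C	U	GCU	GUU	A	V	exon	rpl20eU131AV	.
clpP	73106	324	108	3	C	U	GCC	GCU	A	A	exon	clpPeU324AA	.
petB	77516	296	98	.	C	U	UCA	UUA	S	L	intron	petBiU296SL	.
petB	78586	611	204	2	C	U	CCA	CUA	P	L	exon	petBeU611PL	.
rps3	85153	609	203	3	C	U	AUC	AUU	I	I	exon	rps3eU609II	.
rps3	85423	339	113	3	U	C	GUU	GUC	V	V	exon	rps3eC339VV	.
rps3	85486	276	92	3	C	U	ACC	ACU	T	T	exon	rps3eU276TT	.
rps3	85520	242	81	2	C	U	CCA	CUA	P	L	exon	rps3eU242PL	.
rps3	85710	52	18	1	C	U	CAU	UAU	H	Y	exon	rps3eU52HY	.
rpl23	87527	194	65	2	C	U	ACA	AUA	T	I	exon	rpl23eU194TI	.
ycf2	88475	243	81	1	U	C	UUU	CUU	F	L	exon	ycf2eC243FL	.
ycf2	89627	1395	465	3	G	A	UCG	UCA	S	S	exon	ycf2eA1395SS	.
ycf2	89907	1676	559	2	U	C	UUA	UCA	L	S	exon	ycf2eC1676LS	.
ycf2	90243	2011	671	1	G	A	GAA	AAA	E	K	exon	ycf2eA2011EK	.
ycf2	91075	2843	948	2	C	U	UCC	UUC	S	F	exon	ycf2eU2843SF	.
ndhB	95864	1481	494	2	C	U	CCA	CUA	P	L	exon	ndhBeU1481PL	.
ndhB	96509	830	277	2	C	U	UCA	UUA	S	L	exon	ndhBeU830SL	.
ndhB	97273	737	246	2	C	U	CCA	CUA	P	L	exon	ndhBeU737PL	.
ndhB	97861	149	50	2	C	U	UCA	UUA	S	L	exon	ndhBeU149SL	.
rps12	99558	144	48	3	C	U	GCC	GCU	A	A	exon	rps12eU144AA	.
ndhH	117572	726	242	3	C	U	UAC	UAU	Y	Y	exon	ndhHeU726YY	.
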