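# Codon usage of the sweet potato plastome, transcribed as printed.
# Known irregularities kept verbatim: UAA listed under Tyr; Val row
# lacks GUG.  The anomaly column flags them.
amino_acid	codon	count	anomaly
Ala	GCA	343	.
Ala	GCU	412	.
Ala	GCC	449	.
Ala	GCG	125	.
Cys	UGU	192	.
Cys	UGC	88	.
Asp	GAU	598	.
Asp	GAC	276	.
Glu	GAA	842	.
Glu	GAG	283	.
Phe	UUU	939	.
Phe	UUC	342	.
Gly	GGA	538	.
Gly	GGU	589	.
Gly	GGC	312	.
Gly	GGG	126	.
His	CAU	407	.
His	CAC	131	.
Ile	AUA	546	.
Ile	AUU	1078	.
Ile	AUC	185	.
Lys	AAA	798	.
Lys	AAG	243	.
Thr	ACA	551	.
Thr	ACU	379	.
Thr	ACG	163	.
Thr	ACC	56	.
Met	AUG	526	.
Asn	AAU	749	.
Asn	AAC	190	.
Pro	CCA	329	.
Pro	CCU	358	.
Pro	CCG	252	.
Pro	CCC	56	.
Gln	CAA	537	.
Gln	CAG	242	.
Arg	CGA	312	.
Arg	CGU	334	.
Arg	CGG	87	.
Arg	CGC	68	.
Arg	AGA	408	.
Arg	AGG	140	.
Leu	UUG	405	.
Leu	UUA	694	.
Leu	CUA	476	.
Leu	CUU	382	.
Leu	CUC	270	.
Leu	CUG	103	.
Ser	UCA	681	.
Ser	UCU	477	.
Ser	UCG	309	.
Ser	UCC	187	.
Ser	AGU	302	.
Ser	AGC	70	.
Val	GUU	543	.
Val	GUA	412	.
Val	GUC	286	.
Trp	UGG	380	.
Tyr	UAA	529	stop_codon_listed_under_Tyr
Tyr	UAC	238	.
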