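# Repeat pairs of the sweet potato plastome, transcribed as printed
# (positions verbatim; the printed ranges span size+1 positions).
klass	size	pos1	pos2	loc1	loc2	sequence	anomaly
forward	39	45230-45269	99641-99680	Intron (ycf3)	IGS (rps12-ycf15)	CAGAACCGTACATGAGATTTTCACCTCATACGGCTCCTC	.
forward	38	59760-59798	59784-59822	accD	accD	GAAAGTTCTAATGAGAATGAAAGCGAAAGTTCTAATGA	.
forward	36	40125-40161	42350-42386	psaB	psaA	AATAGCTAAATGATGGTGTGCAATATCGGTCAGCCA	.
forward	22	9654-9676	37813-37835	trnG-GCC	trnG-UCC	GATGCGGGTTCGATTCCCGCTA	.
forward	22	8124-8146	36869-36891	trnS-GCU	trnS-UGA	AGAGAGGGATTCGAACCCTCGG	.
forward	20	54022-54042	144734-144754	trnV-UAC	trnA-UGC	GCTCTACCAACTGAGCTATA	.
forward	20	15073-15093	113223-113243	atpI	IGS (trnN-GUU-rps15)	AAAGAAACAAGAACAACAA	sequence_is_19nt_for_size_20
reverse	26	6039-6065	14796-14822	IGS (rps16-trnQ-UUG)	atpH	TCATGAATAGTCATAGGTTCTATTAT	.
reverse	25	1614-1639	37917-37942	IGS (psbA-matK)	psaB	AAATAAAAAAAAAAAAAAGAATTCT	.
reverse	17	76295-76312	127586-127603	psbT	ndhG	CGGCGAGAAATCTTTAT	.
palindromic	39	45230-45269	149439-149478	Intron (ycf3)	IGS (ycf15-rps12)	CCAGAACCGTACATGAGATTTTCACCTCATACGGCTCCT	.
palindromic	28	8120-8148	46916-46944	trnS-GCU	trnS-GGA	TGGAAAGAGAGGGATTCGAACCCTCGGT	.
palindromic	19	15073-15092	135861-135880	atpI	IGS (rps15-trnN-GUU)	TAAAGAAACAAGAACAACA	.
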