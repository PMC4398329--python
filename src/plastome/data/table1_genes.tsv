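# Gene inventory of the sweet potato plastome.  Protein-coding and
# rRNA rows transcribe the printed gene table (copies/introns per
# its footnotes); tRNA names are synthesized stand-ins consistent
# with the printed copy arithmetic (31 single + 6 duplicated, two
# of them intron-bearing), flagged in the provenance column.
name	kind	group	system	copies	introns	provenance
psaA	CDS	photosynthesis	Photosystem I	1	1	printed
psaB	CDS	photosynthesis	Photosystem I	1	0	printed
psaC	CDS	photosynthesis	Photosystem I	1	0	printed
psaI	CDS	photosynthesis	Photosystem I	1	0	printed
psaJ	CDS	photosynthesis	Photosystem I	1	0	printed
ycf3	CDS	photosynthesis	Photosystem I	1	2	printed
ycf4	CDS	photosynthesis	Photosystem I	1	0	printed
psbA	CDS	photosynthesis	Photosystem II	1	0	printed
psbB	CDS	photosynthesis	Photosystem II	1	0	printed
psbC	CDS	photosynthesis	Photosystem II	1	0	printed
psbD	CDS	photosynthesis	Photosystem II	1	0	printed
psbE	CDS	photosynthesis	Photosystem II	1	0	printed
psbF	CDS	photosynthesis	Photosystem II	1	0	printed
psbG	CDS	photosynthesis	Photosystem II	1	0	printed
psbH	CDS	photosynthesis	Photosystem II	1	0	printed
psbI	CDS	photosynthesis	Photosystem II	1	0	printed
psbJ	CDS	photosynthesis	Photosystem II	1	0	printed
psbK	CDS	photosynthesis	Photosystem II	1	0	printed
psbL	CDS	photosynthesis	Photosystem II	1	0	printed
psbM	CDS	photosynthesis	Photosystem II	1	0	printed
psbN	CDS	photosynthesis	Photosystem II	1	0	printed
psbT	CDS	photosynthesis	Photosystem II	1	1	printed
petA	CDS	photosynthesis	Cytochrome b6/f complex	1	0	printed
petB	CDS	photosynthesis	Cytochrome b6/f complex	1	0	printed
petD	CDS	photosynthesis	Cytochrome b6/f complex	1	0	printed
petG	CDS	photosynthesis	Cytochrome b6/f complex	1	0	printed
petL	CDS	photosynthesis	Cytochrome b6/f complex	1	0	printed
petN	CDS	photosynthesis	Cytochrome b6/f complex	1	0	printed
atpA	CDS	photosynthesis	ATP synthase	1	0	printed
atpB	CDS	photosynthesis	ATP synthase	1	0	printed
atpE	CDS	photosynthesis	ATP synthase	1	0	printed
atpF	CDS	photosynthesis	ATP synthase	1	1	printed
atpH	CDS	photosynthesis	ATP synthase	1	0	printed
atpI	CDS	photosynthesis	ATP synthase	1	0	printed
rbcL	CDS	photosynthesis	Calvin cycle	1	0	printed
ccsA	CDS	photosynthesis	C-type cytochrome synthesis	1	0	printed
ndhA	CDS	chloro-respiration	NADH oxidoreductase	1	1	printed
ndhB	CDS	chloro-respiration	NADH oxidoreductase	2	1	printed
ndhC	CDS	chloro-respiration	NADH oxidoreductase	1	0	printed
ndhD	CDS	chloro-respiration	NADH oxidoreductase	1	0	printed
ndhE	CDS	chloro-respiration	NADH oxidoreductase	1	0	printed
ndhF	CDS	chloro-respiration	NADH oxidoreductase	1	0	printed
ndhG	CDS	chloro-respiration	NADH oxidoreductase	1	0	printed
ndhH	CDS	chloro-respiration	NADH oxidoreductase	2	0	printed
ndhI	CDS	chloro-respiration	NADH oxidoreductase	1	0	printed
ndhJ	CDS	chloro-respiration	NADH oxidoreductase	1	0	printed
ndhK	CDS	chloro-respiration	NADH oxidoreductase	1	0	printed
rpoA	CDS	expression-machinery	RNA polymerase	1	0	printed
rpoB	CDS	expression-machinery	RNA polymerase	1	0	printed
rpoC1	CDS	expression-machinery	RNA polymerase	1	1	printed
rpoC2	CDS	expression-machinery	RNA polymerase	1	0	printed
rpl14	CDS	expression-machinery	ribosomal large subunit	1	0	printed
rpl16	CDS	expression-machinery	ribosomal large subunit	1	0	printed
rpl2	CDS	expression-machinery	ribosomal large subunit	1	0	printed
rpl20	CDS	expression-machinery	ribosomal large subunit	1	0	printed
rpl22	CDS	expression-machinery	ribosomal large subunit	1	0	printed
rpl23	CDS	expression-machinery	ribosomal large subunit	1	0	printed
rpl32	CDS	expression-machinery	ribosomal large subunit	1	0	printed
rpl33	CDS	expression-machinery	ribosomal large subunit	1	0	printed
rpl36	CDS	expression-machinery	ribosomal large subunit	1	0	printed
rps2	CDS	expression-machinery	ribosomal small subunit	1	0	printed
rps3	CDS	expression-machinery	ribosomal small subunit	1	0	printed
rps4	CDS	expression-machinery	ribosomal small subunit	1	0	printed
rps7	CDS	expression-machinery	ribosomal small subunit	2	0	printed
rps8	CDS	expression-machinery	ribosomal small subunit	1	0	printed
rps11	CDS	expression-machinery	ribosomal small subunit	1	0	printed
rps12	CDS	expression-machinery	ribosomal small subunit	2	1	printed
rps14	CDS	expression-machinery	ribosomal small subunit	1	0	printed
rps15	CDS	expression-machinery	ribosomal small subunit	2	0	printed
rps16	CDS	expression-machinery	ribosomal small subunit	1	0	printed
rps18	CDS	expression-machinery	ribosomal small subunit	1	0	printed
rps19	CDS	expression-machinery	ribosomal small subunit	1	0	printed
matK	CDS	expression-machinery	maturase K	1	0	printed
accD	CDS	metabolic-pathway	acetyl-CoA carboxylase carboxyltransferase	1	0	printed
clpP	CDS	metabolic-pathway	clp protease proteolytic subunit	1	0	printed
cemA	CDS	metabolic-pathway	chloroplast envelope membrane protein	1	0	printed
ycf2	CDS	pseudogene	unknown functions	2	0	printed
ycf15	CDS	pseudogene	unknown functions	2	0	printed
ycf68	CDS	pseudogene	unknown functions	2	0	printed
lhbA	CDS	pseudogene	unknown functions	1	0	printed
orf42	CDS	pseudogene	unknown functions	2	0	printed
orf56	CDS	pseudogene	unknown functions	2	1	printed
orf188	CDS	pseudogene	unknown functions	2	0	printed
trnH-GUG	tRNA	.	.	1	0	synthesized
trnK-UUU	tRNA	.	.	1	1	synthesized
trnQ-UUG	tRNA	.	.	1	0	synthesized
trnS-GCU	tRNA	.	.	1	0	synthesized
trnG-GCC	tRNA	.	.	1	0	synthesized
trnG-UCC	tRNA	.	.	1	0	synthesized
trnR-UCU	tRNA	.	.	1	0	synthesized
trnC-GCA	tRNA	.	.	1	0	synthesized
trnD-GUC	tRNA	.	.	1	0	synthesized
trnY-GUA	tRNA	.	.	1	0	synthesized
trnE-UUC	tRNA	.	.	1	0	synthesized
trnT-GGU	tRNA	.	.	1	0	synthesized
trnS-UGA	tRNA	.	.	1	0	synthesized
trnfM-CAU	tRNA	.	.	1	0	synthesized
trnS-GGA	tRNA	.	.	1	0	synthesized
trnT-UGU	tRNA	.	.	1	0	synthesized
trnL-UAA	tRNA	.	.	1	1	synthesized
trnF-GAA	tRNA	.	.	1	0	synthesized
trnV-UAC	tRNA	.	.	1	0	synthesized
trnM-CAU	tRNA	.	.	1	0	synthesized
trnW-CCA	tRNA	.	.	1	0	synthesized
trnP-UGG	tRNA	.	.	1	0	synthesized
trnL-UAG	tRNA	.	.	1	0	synthesized
trnN-GUU	tRNA	.	.	1	0	synthesized
trnR-CCG	tRNA	.	.	1	0	synthesized
trnL-GAG	tRNA	.	.	1	0	synthesized
trnV-AAC	tRNA	.	.	1	0	synthesized
trnR-CCU	tRNA	.	.	1	0	synthesized
trnP-GGG	tRNA	.	.	1	0	synthesized
trnL-CAG	tRNA	.	.	1	0	synthesized
trnV-CAC	tRNA	.	.	1	0	synthesized
trnI-CAU	tRNA	.	.	2	0	synthesized
trnL-CAA	tRNA	.	.	2	0	synthesized
trnV-GAC	tRNA	.	.	2	0	synthesized
trnI-GAU	tRNA	.	.	2	0	synthesized
trnA-UGC	tRNA	.	.	2	0	synthesized
trnR-ACG	tRNA	.	.	2	0	synthesized
rrn23	rRNA	.	.	2	0	printed
rrn16	rRNA	.	.	2	0	printed
rrn5	rRNA	.	.	2	0	printed
rrn4.5	rRNA	.	.	2	0	printed
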