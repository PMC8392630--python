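chrS1	synth	transcript	190001	230000	.	+	.	gene_id "GENEA"; transcript_id "GENEA.1"; gene_biotype "protein_coding";
chrS1	synth	exon	190001	191000	.	+	.	gene_id "GENEA"; transcript_id "GENEA.1"; gene_biotype "protein_coding";
chrS1	synth	exon	210001	211000	.	+	.	gene_id "GENEA"; transcript_id "GENEA.1"; gene_biotype "protein_coding";
chrS1	synth	exon	229001	230000	.	+	.	gene_id "GENEA"; transcript_id "GENEA.1"; gene_biotype "protein_coding";
chrS1	synth	five_prime_utr	190001	190200	.	+	.	gene_id "GENEA"; transcript_id "GENEA.1"; gene_biotype "protein_coding";
chrS1	synth	three_prime_utr	229801	230000	.	+	.	gene_id "GENEA"; transcript_id "GENEA.1"; gene_biotype "protein_coding";
chrS1	synth	transcript	345001	355000	.	+	.	gene_id "GENEB"; transcript_id "GENEB.1"; gene_biotype "protein_coding";
chrS1	synth	exon	345001	345400	.	+	.	gene_id "GENEB"; transcript_id "GENEB.1"; gene_biotype "protein_coding";
chrS1	synth	exon	350001	351000	.	+	.	gene_id "GENEB"; transcript_id "GENEB.1"; gene_biotype "protein_coding";
chrS1	synth	exon	354001	355000	.	+	.	gene_id "GENEB"; transcript_id "GENEB.1"; gene_biotype "protein_coding";
chrS1	synth	transcript	500801	520000	.	+	.	gene_id "GENEC"; transcript_id "GENEC.1"; gene_biotype "protein_coding";
chrS1	synth	exon	500801	501500	.	+	.	gene_id "GENEC"; transcript_id "GENEC.1"; gene_biotype "protein_coding";
chrS1	synth	exon	519001	520000	.	+	.	gene_id "GENEC"; transcript_id "GENEC.1"; gene_biotype "protein_coding";
chrS1	synth	transcript	630001	650400	.	+	.	gene_id "GENED"; transcript_id "GENED.1"; gene_biotype "protein_coding";
chrS1	synth	exon	630001	631000	.	+	.	gene_id "GENED"; transcript_id "GENED.1"; gene_biotype "protein_coding";
chrS1	synth	exon	649001	650400	.	+	.	gene_id "GENED"; transcript_id "GENED.1"; gene_biotype "protein_coding";
chrS1	synth	transcript	799001	802000	.	-	.	gene_id "GENEE"; transcript_id "GENEE.1"; gene_biotype "lncRNA";
chrS1	synth	exon	799501	801000	.	-	.	gene_id "GENEE"; transcript_id "GENEE.1"; gene_biotype "lncRNA";
chrS1	synth	transcript	940001	960000	.	-	.	gene_id "GENEF"; transcript_id "GENEF.1"; gene_biotype "processed_pseudogene";
chrS1	synth	exon	940001	941000	.	-	.	gene_id "GENEF"; transcript_id "GENEF.1"; gene_biotype "processed_pseudogene";
chrS1	synth	exon	959001	960000	.	-	.	gene_id "GENEF"; transcript_id "GENEF.1"; gene_biotype "processed_pseudogene";
chrS1	synth	transcript	1240001	1260000	.	-	.	gene_id "GENEG"; transcript_id "GENEG.1"; gene_biotype "snoRNA";
chrS1	synth	exon	1240001	1241000	.	-	.	gene_id "GENEG"; transcript_id "GENEG.1"; gene_biotype "snoRNA";
chrS1	synth	exon	1259001	1260000	.	-	.	gene_id "GENEG"; transcript_id "GENEG.1"; gene_biotype "snoRNA";
chrS2	synth	transcript	100001	140000	.	+	.	gene_id "GENEH"; transcript_id "GENEH.1"; gene_biotype "protein_coding";
chrS2	synth	exon	100001	101000	.	+	.	gene_id "GENEH"; transcript_id "GENEH.1"; gene_biotype "protein_coding";
chrS2	synth	exon	139001	140000	.	+	.	gene_id "GENEH"; transcript_id "GENEH.1"; gene_biotype "protein_coding";
chrS2	synth	transcript	500001	510000	.	-	.	gene_id "GENEI"; transcript_id "GENEI.1"; gene_biotype "miRNA";
chrS2	synth	exon	500001	510000	.	-	.	gene_id "GENEI"; transcript_id "GENEI.1"; gene_biotype "miRNA";
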