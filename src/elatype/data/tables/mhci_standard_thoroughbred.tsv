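# Standard-allele content of MHCI haplotypes, Thoroughbred cohort (n=96).
# occurrences: haplotype slots in the cohort (homozygotes count twice).
# alleles: semicolon-separated, Eqca- prefix omitted as printed.
haplotype	occurrences	total_expressed	n_standard	alleles
HP1.1a	30	11	5	4*001:AA;N*001:01;MHCI*gb8:02;16*001:01;MHCI*gb6:03
HP1.1b	7	10	5	MHCI*gb38:01;N*001:01;MHCI*gb8:02;16*001:AA;MHCI*gb6:04
HP1.2	42	12	7	MHCI*gb12:01;MHCI*gb50:01;MHCI*gb2:01;MHCI*gb4:01;MHCI*gb27:01;6*001:01;MHCI*gb25:01
HP1.3	27	13	8	MHCI*gb38:01;MHCI*gb40:01;1*002:02;16*003:01;MHCI*gb16:01;MHCI*gb1:02;MHCI*gb4:02;MHCI*gb27:01
HP1.4	16	16	10	MHCI*gb5:01;N*005:AA;1*003:AA;MHCI*gb19:01;MHCI*gb6:01;MHCI*gb15:01;MHCI*gb12:02;MHCI*gb4:02;6*001:01;MHCI*gb25:01
HP1.5	13	12	7	MHCI*gb38:01;MHCI*gb21:01;MHCI*gb22:01;1*005:02;MHCI*gb23:01;MHCI*gb15:01;MHCI*gb1:01
HP1.6a	34	15	8	MHCI*gb31:01;4*001:01;1*001:01;3*001:01;MHCI*gb6:02;MHCI*gb18:01;6*001:01;MHCI*gb25:01
HP1.6b	11	11	5	4*001:01;1*001:01;3*001:01;MHCI*gb6:02;MHCI*gb18:01
HP1.7a	2	12	7	MHCI*gb37:01;MHCI*gb36:01;MHCI*gb8:01;MHCI*gb30:01;MHCI*gb1:02;MHCI*gb4:02;6*001:01
HP1.8	3	16	10	MHCI*gb7:03;4*001:AA:01;MHCI*gb29:01;MHCI*gb3:01;MHCI*gb5:02;MHCI*gb1:02;MHCI*gb4:02;MHCI*gb27:01;6*001:01;MHCI*gb25:01
HP1.9	2	8	4	MHCI*gb38:01;MHCI*gb7:02;MHCI*gb34:01;MHCI*gb35:01
HP1.10	2	6	2	MHCI*gb3:02;MHCI*gb49:01
unHP1.11	1	13	7	MHCI*gb43:01;MHCI*gb47:01;MHCI*gb10:01;MHCI*gb48:01;MHCI*gb30:01;MHCI*gb4:02;MHCI*gb27:01
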