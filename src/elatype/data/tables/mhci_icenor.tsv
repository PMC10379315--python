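# Standard-allele content of MHCI haplotypes, Icelandic (n=35) and Norwegian
# Fjord (n=37) horse cohorts. Only the Eqca-2 universal alleles could be
# reliably placed on haplotypes in this cohort (universal_allele column).
haplotype	occ_icelandic	occ_norwegian	n_standard	alleles	universal_allele
HP1.10	6	4	2	MHCI*gb3:02;MHCI*gb49:01
HP1.12	2	1	7	1*001:AA;MHCI*no34:01;MHCI*gb1:02;MHCI*no6:01;MHCI*gb6:05;4*001:AB;3*001:01	2*001:01
HP1.13	3	0	6	N*006:01;MHCI*no5:01;MHCI*no3:02;MHCI*gb8:03;MHCI*gb6:05;6*001:01	2*001:AC
HP1.14	2	0	7	MHCI*no25:01;MHCI*gb34:01;MHCI*no3:02;MHCI*gb40:01;MHCI*gb6:05;1*002:AA;MHCI*gb1:02	2*001:AA
HP1.15	3	0	5	MHCI*no17:01;MHCI*no1:02;MHCI*gb1:02:02;MHCI*gb49:02;3*001:AA
HP1.16	8	0	6	MHCI*no16:01;MHCI*no28:01;MHCI*gb15:01;MHCI*gb34:02;MHCI*gb6:03;MHCI*gb49:04
HP1.17	0	2	5	MHCI*no29:01;MHCI*no1:02;MHCI*no3:01;MHCI*gb8:05;MHCI*gb6:05
unHP1.18a	1	0	4	MHCI*gb1:01;MHCI*no2:02;MHCI*gb34:01;MHCI*no32:01	2*001:AI
unHP1.18b	1	0	4	MHCI*gb1:01;MHCI*no2:01;MHCI*gb34:01;MHCI*no32:01	2*001:AI
HP1.19a	0	16	6	MHCI*no24:01;MHCI*no9:01;MHCI*gb2:01;MHCI*gb4:03;MHCI*gb15:03;MHCI*gb10:02	2*001:AJ
HP1.19b	1	19	7	MHCI*no24:01;MHCI*no9:01;MHCI*no12:01;MHCI*gb4:03;MHCI*gb6:03;MHCI*gb15:03;3*001:AA	2*001:AJ
HP1.20	3	3	5	MHCI*gb41:01;MHCI*no31:01;MHCI*gb4:02;MHCI*gb1:01;MHCI*gb12:03	2*003:01
HP1.21	0	9	4	MHCI*no35:01;MHCI*no19:01;MHCI*gb1:01;MHCI*gb10:01	2*001:AM
HP1.22	0	5	4	MHCI*gb43:01:01;MHCI*gb36:02;MHCI*gb3:01;MHCI*gb4:02	2*003:01
HP1.23	3	0	4	MHCI*no31:01;MHCI*no7:01;MHCI*gb4:02;MHCI*gb12:03	2*003:01
HP1.24	19	0	7	MHCI*no23:01;MHCI*is1:01:01;MHCI*gb4:02;MHCI*gb15:01;MHCI*no8:01;MHCI*gb1:02:02;3*001:AC	2*001:03
HP1.25	3	0	6	MHCI*no13:01;MHCI*no4:01;MHCI*no22:01;MHCI*gb7:06;MHCI*gb1:05;MHCI*gb1:03	2*001:03
HP1.26	5	10	7	MHCI*no1:01;MHCI*no18:01;MHCI*gb8:02;MHCI*gb15:02;MHCI*gb49:02;3*001:AA;MHCI*gb7:04	2*001:AB
HP1.27	1	2	5	N*001:01;MHCI*gb8:02;16*001:AA;2*001:AB;MHCI*gb27:01
HP1.28	5	0	8	MHCI*no21:01;MHCI*no15:01;MHCI*gb6:01;MHCI*gb19:01;MHCI*gb15:02;3*001:AD;MHCI*gb1:02;6*001:01	2*001:03
unHP1.30	1	0	7	16*003:01;1*002:02;3*001:AA:01;MHCI*gb15:03;MHCI*gb40:01;MHCI*gb12:03;MHCI*gb1:01:01	2*001:03
unHP1.31	1	0	8	MHCI*gb5:02;MHCI*gb29:01;MHCI*gb1:02;MHCI*gb15:01;MHCI*gb4:02;MHCI*gb7:05;MHCI*gb1:05;3*001:AB
unHP1.32	0	1	6	MHCI*no4:02;MHCI*no20:01;MHCI*gb41:02;MHCI*gb21:01;MHCI*gb1:01;6*001:01	2*001:AC
unHP1.33	1	0	7	MHCI*no30:01;MHCI*no33:01;MHCI*gb15:01;MHCI*no36:01;MHCI*gb49:03;MHCI*gb7:06;MHCI*no37:01	2*001:AL
unHP1.7b	1	0	7	MHCI*gb37:01;MHCI*gb36:02;MHCI*gb8:01;MHCI*gb30:01;MHCI*gb1:02;MHCI*gb4:02;MHCI*gb10:01	2*001:AH
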