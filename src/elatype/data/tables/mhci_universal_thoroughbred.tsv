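# Universal-allele content of MHCI haplotypes, Thoroughbred cohort (n=96).
# A leading "?" marks alleles whose presence on the haplotype could not be
# confirmed because of their promiscuity; they are still counted in n_universal.
haplotype	occurrences	total_expressed	n_universal	alleles
HP1.1a	30	11	6	MHCI*gb11:01:02;2*001:AB;MHCI*gb13:01;7*001:01;MHCI*gb9:01;MHCI*gb26:01
HP1.1b	7	10	5	MHCI*gb11:02;2*001:AB;MHCI*gb13:02;7*002:01:AA;MHCI*gb26:01
HP1.2	42	12	5	2*001:AE;MHCI*gb13:01;7*001:01;MHCI*gb9:01;MHCI*gb26:01
HP1.3	27	13	5	MHCI*gb11:01:02;2*001:03;MHCI*gb13:01;7*001:01;MHCI*gb26:01
HP1.4	16	16	6	MHCI*gb11:01:01;2*001:AD;MHCI*gb13:01;7*001:01;MHCI*gb9:01;MHCI*gb26:01
HP1.5	13	12	5	MHCI*gb11:01:02;2*001:AC;MHCI*gb13:01;7*002:01:AA;MHCI*gb26:01
HP1.6a	34	15	7	MHCI*gb11:01:02;2*001:01;MHCI*gb13:03;MHCI*gb13:02;7*002:01:AA;MHCI*gb9:01;MHCI*gb26:01
HP1.6b	11	11	6	MHCI*gb11:01:02;2*001:01;MHCI*gb13:01;7*001:01;MHCI*gb9:01;MHCI*gb26:01
HP1.7a	2	12	5	?MHCI*gb11:01:02;2*001:AH;7*001:01;MHCI*gb9:02;?MHCI*gb26:01
HP1.8	3	16	6	?MHCI*gb11:01:02;2*003:01;MHCI*gb13:01;7*001:01;MHCI*gb9:01;?MHCI*gb26:01
HP1.9	2	8	4	?MHCI*gb11:01:02;2*001:AA;7*002:01:AA;?MHCI*gb26:01
HP1.10	2	6	4	MHCI*gb11:01:01;MHCI*gb13:01;MHCI*gb9:01;?MHCI*gb26:01
unHP1.11	1	13	6	?MHCI*gb11:01:02;2*003:01;MHCI*gb13:01;7*001:01;MHCI*gb9:02;?MHCI*gb26:01
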