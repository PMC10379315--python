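# Gene content of MHCII haplotypes, Thoroughbred cohort (n=96).
# Dual designations within one cell are slash-separated (one gene).
# A leading "?" marks the promiscuous DRB3 allele whose presence on the
# haplotype could not be confirmed; "?" cells are excluded from the printed
# n_expressed count.
haplotype	occurrences	n_expressed	dqa1	dqa2	dqb1	dqb2	dra	drb1	drb2	drb3
HP2.1	40	8	DQA1*001:01	DQA2*001:01	DQB*gb2:01	DQB*gb3:01	DRA*001:01/DRA*001:04	DRB1*001:01	DRB2*002:01	DRB3*001:01:02/DRB3*001:01:01
HP2.2a	42	8	DQA1*002:03	DQA*gb1:01	DQB1*006:01	DQB2*003:01	DRA*001:02	DRB1*003:01	DRB2*001:01/DRB2*001:02	DRB3*001:01:02/DRB3*001:01:01
HP2.2b	2	8	DQA1*002:03	DQA*gb1:01	DQB1*006:01	DQB2*003:01	DRA*001:02	DRB1*003:01	DRB2*002:01	DRB3*001:01:02/DRB3*001:01:01
HP2.2c	5	8	DQA1*002:03	DQA*gb1:01	DQB1*006:01	DQB2*003:01	DRA*001:02	DRB1*003:01	DRB2*005:01	DRB3*002:01/DRB3*002:02
HP2.3	38	8	DQA1*002:01	DQA*gb4:01	DQB1*002:01	DQB2*002:01	DRA*001:01/DRA*001:04	DRB1*002:01	DRB2*003:01	DRB3*001:01:02/DRB3*001:01:01
HP2.4a	28	7	DQA1*003:01	DQA2*002:01	DQB1*004:01	DQB2*004:01	DRA*001:03	DRB1*004:01	DRB2*004:01
unHP2.4b	1	7	DQA1*003:01	DQA2*002:01	DQB1*004:01	DQB2*004:01	DRA*001:01/DRA*001:04	DRB1*004:01	DRB2*004:01
HP2.4c	3	7	DQA1*003:01	DQA2*002:01	DQB1*004:01	DQB2*004:01	DRA*001:02	DRB1*003:01	DRB2*004:01
HP2.5	21	7	DQA1*004:01		DQB1*005:01	DQB2*005:01	DRA*001:01/DRA*001:04	DRB1*005:01	DRB2*001:01/DRB2*001:02	DRB3*002:01/DRB3*002:02
HP2.6a	3	7	DQA1*002:02	DQA2*002:01	DQB1*007:01	DQB2*004:01	DRA*001:01/DRA*001:04	DRB*gb1:01	DRB*gb2:01	?DRB3*001:01:02/DRB3*001:01:01
HP2.6b	2	8	DQA1*002:02	DQA2*002:01	DQB1*007:01	DQB2*004:01	DRA*001:02	DRB1*003:01	DRB*gb2:01	DRB3*001:01:02/DRB3*001:01:01
HP2.7	3	8	DQA1*002:05	DQA*gb3:01	DQB1*003:AA	DQB2*003:01	DRA*001:01/DRA*001:04	DRB1*007:01/DRB1*007:02	DRB2*002:01	DRB3*001:01:02/DRB3*001:01:01
HP2.8	2	7	DQA*gb2:01	DQA2*002:AA	DQB*gb1:01	DQB*gb4:01	DRA*001:03	DRB*gb2:01		DRB3*002:01/DRB3*002:02
unHP2.9a	1	7	DQA1*005:01	DQA*gb1:04	DQB*gb5:01	DQB2*003:01	DRA*001:03	DRB1*008:01	DRB2*006:01	?DRB3*001:01:02/DRB3*001:01:01
unHP2.10	1	7	DQA1*002:02	DQA*gb1:01	DQB1*003:01	DQB2*003:01	DRA*001:03	DRB*gb3:01	DRB2*001:01/DRB2*001:02	?DRB3*001:01:02/DRB3*001:01:01
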