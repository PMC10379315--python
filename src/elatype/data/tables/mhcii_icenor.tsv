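# Gene content of MHCII haplotypes, Icelandic (n=35) and Norwegian Fjord
# (n=37) horse cohorts. Dual designations within one cell are slash-separated
# (one gene). A leading "?" marks the DRA allele of unHP2.28b, which was
# assumed rather than directly confirmed; a leading "!" marks the dqb3 cell of
# unHP2.31, which prints a DRB2 designation — stored verbatim with a typo
# flag; class counts exclude "!" cells.
haplotype	occ_icelandic	occ_norwegian	n_expressed	dqa1	dqa2	dqa3	dqb1	dqb2	dqb3	dra	drb1	drb2	drb3
HP2.5	0	2	7	DQA1*004:01			DQB1*005:01	DQB2*005:01		DRA*001:01/DRA*001:04	DRB1*005:01	DRB2*001:01/DRB2*001:02	DRB3*002:01/DRB3*002:02
HP2.9b	3	0	8	DQA1*005:01	DQA*gb1:04		DQB*gb5:01	DQB2*003:01		DRA*001:01/DRA*001:04	DRB1*007:01/DRB1*007:02	DRB2*006:01	DRB3*002:01/DRB3*002:02
HP2.11	9	2	6	DQA*no1:01	DQA1*002:01:AA		DQB1*007:AA	DQB*no1:01		DRA*001:01/DRA*001:04	DRB*is10:01
HP2.12	3	0	8	DQA1*002:03	DQA*gb1:01		DQB*gb1:03	DQB2*003:AA		DRA*001:01/DRA*001:04	DRB*is6:01	DRB2*002:01:AA	DRB3*001:01:02/DRB3*001:01:01
HP2.13	2	1	7	DQA*gb1:06			DQB*is3:01	DQB2*002:AA		DRA*001:03	DRB*gb3:01	DRB*gb2:01	DRB3*002:01/DRB3*002:02
HP2.14	4	17	6	DQA1*002:02	DQA*gb1:02		DQB*no9:01	DQB2*003:01		DRA*001:01/DRA*001:04	DRB*gb1:01
HP2.15	6	0	7	DQA*gb2:01	DQA2*002:AA		DQB*gb1:01	DQB*gb4:01		DRA*001:01/DRA*001:04	DRB*is6:01		DRB3*001:01:02/DRB3*001:01:01
HP2.16a	8	0	8	DQA1*002:AA	DQA*gb1:05:04		DQB1*006:AA	DQB2*002:AB		DRA*001:01/DRA*001:04	DRB*is8:01	DRB2*002:01:AA	DRB3*002:01/DRB3*002:02
unHP2.16b	1	0	7	DQA1*002:AA	DQA*gb1:05:04		DQB1*006:AA	DQB2*002:AB		DRA*001:01/DRA*001:04	DRB*is8:01	DRB2*002:AA
HP2.17	3	0	6	DQA*is4:01	DQA*gb3:01		DQB*is4:01			DRA*001:01/DRA*001:04	DRB*is9:01	DRB2*004:01
HP2.18	0	4	7	DQA*no1:01			DQB*no7:01	DQB*no4:01		DRA*001:01/DRA*001:04	DRB*no7:01	DRB2*003:01	DRB3*002:01/DRB3*002:02
HP2.19a	4	0	8	DQA*is5:01	DQA*gb1:01	DQA*is3:01	DQB*is8:01	DQB*is2:01		DRA*001:01/DRA*001:04	DRB1*002:01	DRB2*005:01
HP2.19b	2	0	8	DQA*is5:01	DQA*gb1:01	DQA*is3:01	DQB*is8:01	DQB*is2:01		DRA*001:01/DRA*001:04	DRB1*001:01	DRB2*002:01
HP2.20	4	0	8	DQA1*002:01	DQA*gb1:02		DQB1*007:AB	DQB2*003:01		DRA*001:01/DRA*001:04	DRB*no7:01	DRB2*001:01/DRB2*001:02	DRB3*002:01/DRB3*002:02
HP2.21	1	3	7	DQA*no3:01	DQA2*002:01		DQB*no5:01	DQB2*004:01		DRA*001:01/DRA*001:04	DRB*no8:01	DRB2*002:01
HP2.22a	0	2	9	DQA*no2:01	DQA*gb3:01	DQA*no5:01	DQB*no8:01	DQB*no10:01		DRA*001:01/DRA*001:04	DRB*no1:01:01	DRB*no6:01	DRB3*002:01/DRB3*002:02
unHP2.22b	0	1	9	DQA*no2:01	DQA*gb3:01	DQA*no5:01	DQB*no8:01	DQB*no10:01		DRA*001:01/DRA*001:04	DRB*no1:03	DRB*no6:01	DRB3*002:01/DRB3*002:02
unHP2.22c	0	1	9	DQA*no2:01	DQA*gb3:01	DQA*no5:01	DQB*no8:01	DQB*no10:01		DRA*001:01/DRA*001:04	DRB*no1:02	DRB*no6:01	DRB3*002:01/DRB3*002:02
HP2.23a	0	17	6	DQA*no1:01			DQB*no1:01	DQB*no6:01		DRA*001:01/DRA*001:04	DRB1*002:01		DRB3*002:01/DRB3*002:02
unHP2.23b	0	1	7	DQA*no1:01			DQB*no1:01	DQB*no6:01		DRA*001:01/DRA*001:04	DRB1*002:01	DRB2*002:01	DRB3*001:01:02/DRB3*001:01:01
HP2.23c	0	2	7	DQA*no1:01			DQB*no1:01	DQB*no6:01		DRA*001:01/DRA*001:04	DRB1*002:01	DRB2*002:01	DRB3*002:AA
unHP2.23d	1	0	7	DQA*no1:01			DQB*no1:03	DQB*no6:01		DRA*001:01/DRA*001:04	DRB1*002:01	DRB2*002:01	DRB3*001:01:02/DRB3*001:01:01
HP2.24	0	5	8	DQA1*002:05	DQA2*002:AA		DQB1*003:01	DQB*no1:02		DRA*001:03	DRB1*008:01	DRB2*002:01	DRB3*002:01/DRB3*002:02
HP2.25a	0	11	7	DQA*gb1:05:03	DQA*no4:01		DQB*no11:01	DQB*is7:01	DQB*is1:03	DRA*001:AA		DRB2*004:01
HP2.25b	4	0	7	DQA*gb1:05:03	DQA*no4:01		DQB*no11:01	DQB*is7:01	DQB*is1:02	DRA*001:AA		DRB2*005:01
unHP2.25c	1	0	6	DQA*gb1:05:03	DQA*no4:01		DQB*no11:01	DQB*is8:01		DRA*001:AA		DRB2*005:01
pHP2.26	0	2	3				DQB*no7:01	DQB*no4:01		DRA*001:01/DRA*001:04	DRB*no7:01
unHP2.27	1	0	10	DQA*is5:01	DQA*gb1:01	DQA*is3:01	DQB*no11:01	DQB*is7:01	DQB*is1:02	DRA*001:01/DRA*001:04	DRB1*001:01	DRB2*002:01	DRB3*002:01/DRB3*002:02
unHP2.28a	1	0	5	DQA*gb2:02			DQB*gb1:02			DRA*001:AA	DRB*is10:01	DRB2*002:AA
unHP2.28b	1	0	4	DQA*gb2:02			DQB*gb1:02			?DRA*001:01/DRA*001:04	DRB*is12:01	DRB2*002:AA
unHP2.29	1	0	8	DQA*no1:01	DQA1*002:01:AA		DQB*no7:01	DQB*no4:01		DRA*001:01/DRA*001:04	DRB1*001:01	DRB2*002:AA	DRB3*002:01/DRB3*002:02
unHP2.30	1	0	7	DQA*no2:01	DQA*gb1:01		DQB*is6:01	DQB*is7:01	DQB*is1:01	DRA*001:AA		DRB2*002:AA
unHP2.31	1	0	7	DQA*gb1:05:01			DQB*no11:01	DQB*is7:01	!DRB2*002:01	DRA*001:AA		DRB*no2:01:02	DRB3*002:01/DRB3*002:02
unHP2.32	1	0	7	DQA*gb1:05:02	DQA*is2:01		DQB*is5:01	DQB2*002:AA		DRA*001:AA	DRB1*001:01	DRB*gb2:02
unHP2.33a	1	0	8	DQA*gb2:02	DQA1*002:01:AA	DQA*gb1:03	DQB*gb1:02	DQB2*003:01		DRA*001:01/DRA*001:04	DRB*is12:01	DRB2*002:AA
unHP2.33b	1	0	8	DQA*gb2:02	DQA*gb2:01	DQA*gb1:02	DQB*gb1:02	DQB2*003:01		DRA*001:01/DRA*001:04	DRB*is12:01	DRB2*002:AA
unHP2.34	1	0	7	DQA*gb2:03	DQA2*002:AA		DQB1*003:AA	DQB*no1:02		DRA*001:01/DRA*001:04	DRB1*002:01	DRB2*002:01
unHP2.35	1	0	6		DQA*gb3:01		DQB1*003:AA			DRA*001:03	DRB1*008:01	DRB2*002:01	DRB3*001:01:02/DRB3*001:01:01
unHP2.36	1	0	6	DQA*is4:01			DQB*is4:01	DQB*is9:01		DRA*001:01/DRA*001:04	DRB*is9:01		DRB3*002:AA
unHP2.37	1	0	7	DQA1*002:01	DQA*gb1:02		DQB*no9:01	DQB2*003:01		DRA*001:01/DRA*001:04	DRB*no7:01	DRB2*005:01
unHP2.38	0	1	7	DQA1*002:02	DQA2*002:01		DQB2*004:01:AA	DQB1*004:AA		DRA*001:01/DRA*001:04	DRB*is8:01	DRB2*002:01	DRB3*002:01/DRB3*002:02
unHP2.39	0	1	8	DQA*gb1:05:03	DQA*no4:01		DQB*no7:01	DQB*no4:01		DRA*001:01/DRA*001:04	DRB*no7:01	DRB2*003:01	DRB3*002:01/DRB3*002:02
unpHP2.40	1	0	2							DRA*001:03	DRB*is11:01
unpHP2.41	0	1	4				DQB*no7:01			DRA*001:01/DRA*001:04	DRB*no7:01	DRB2*003:01
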