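# Relative cloning frequencies (%) of gag-amplicon cDNA sequences assignable to unique
# HERV-K(HML-2) loci, by tissue group, from a published Sanger-sequencing survey of HML-2
# transcription in ALS and control CNS tissue. Blank cell = locus not observed in that group.
# Column placement of sparse rows was reconstructed from the per-column clone totals
# (every percentage must equal round-half-up(100*k/total, 2) for an integer count k and
# column counts must sum to the totals); the reconstruction is unique.
#total_sequences	ALS_motor=318	ALS_occi=134	ALS_sc=70	Ctrl_motor=138	Ctrl_occi=96	Ctrl_sc=64
#n_samples	ALS_motor=11	ALS_occi=6	ALS_sc=2	Ctrl_motor=5	Ctrl_occi=2	Ctrl_sc=2
locus_id	ALS_motor	ALS_occi	ALS_sc	Ctrl_motor	Ctrl_occi	Ctrl_sc	provirus_type	env_aa	rec_np9	hg19_anchor
chr1p31.1_K-1	1.57	1.49		2.90	4.17	1.56	1	606	Np9	chr1:75844857
chr1q22_K-7	0.31		1.43	0.72			1	606	Np9	chr1:155603549
chr3p12.3_K-*					1.04		2	242		chr3:75601670
chr3q12.3_K-5	52.20	39.55	58.57	60.14	52.08	64.06	1	263	Np9	chr3:101412824
chr3q13.2_K-3						1.56	1	434	Np9	chr3:112750203
chr3q21.2_K-4	11.01	15.67	7.14	13.04	13.54	1.56	2		Rec	chr3:125611223
chr4p16.1a_K-*	0.63			0.72	1.04		2	158		chr4:9125672
chr4p16.1b_K-*	0.31		1.43		2.08	1.56	2	342	longer	chr4:9661733
chr5q33.3_K-10	1.57	5.22	5.71	0.72			1	139 (969)		chr5:156091809
chr7p22.1_K-6	0.63						2	699 (f-l)	Rec	chr7:4637944
chr7q22.2_K-14	0.94	1.49	2.86	2.17	1.04	3.13		del		chr7:104392150
chr7q34_K-15	8.49	9.70	8.57	9.42	10.42	4.69		del		chr7:141454695
chr8p23.1a_K-*	3.46	10.45			1.04		2	264		chr8:12081367
chr8p23.1b_K-*	5.35	2.24				7.81	2	264		chr8:12323877
chr10p14_K-16	1.89	2.99	2.86	2.17		7.81	2	286	Rec	chr10:6873520
chr11q12.3_K-27	2.83	2.99		3.62	3.13	6.25	2	337		chr11:62148198
chr11q22.1_K-25	0.94						2	661		chr11:101567880
chr19q13.12_K-29	6.92	8.21	11.43	3.62	10.42		2	206		chr19:37604891
chr21q21.1_K-23	0.31			0.72			1	197	Np9	chr21:19940039
chr22q11.21_K-24	0.63						1	606	Np9	chr22:18934451
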