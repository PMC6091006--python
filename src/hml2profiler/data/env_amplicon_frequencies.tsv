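# Relative cloning frequencies (%) and locus origins of cDNA sequences from an env gene
# 5' region amplicon (spans the 292-bp type 1/2 indel), per sample, from the same published
# survey. Composite rows ("A|B") are sequence sets not assignable with confidence to either
# of two near-identical loci. Blank cell = not observed.
#total_sequences	89-Mot=16	62-Mot=40	64-Mot=10	802-SC=25	1509-Mot=13	73-Mot=15	4263-SC=25
#condition	89-Mot=ALS	62-Mot=ALS	64-Mot=ALS	802-SC=ALS	1509-Mot=control	73-Mot=control	4263-SC=control
locus_id	89-Mot	62-Mot	64-Mot	802-SC	1509-Mot	73-Mot	4263-SC	provirus_type	env_aa	rec_np9	hg19_anchor
chr1p31.1_K-1				4.00	7.69		4.00	1	606	Np9	chr1:75844857
chr1q23.3_K-18				4.00				1	553		chr1:160667241
chr3q12.3_K-5	62.50	77.50	70.00	28.00	53.85	40.00	40.00	1	263	Np9	chr3:101412824
chr3q13.2_K-3	6.25	2.50			7.69	6.67	4.00	1	434	Np9	chr3:112750203
chr3q21.2_K-4						13.33		2		Rec	chr3:125611223
chr5q33.3_K-10				8.00				1			chr5:156091809
chr11q23.3_K-20						6.67		1	431		chr11:118594283
chr19q11_K-19						6.67		2	699		chr19:28131235
Venter		7.50	10.00	28.00	15.38		20.00	1	452
chr1q22_K-7|chr5q33.3_K-10	31.25	12.50	20.00	24.00	15.38	13.33	32.00				chr1:155598877-155599165/chr5:156087137-156087425
chr8p23.1a_K-*|chr8p23.1b_K-*				4.00		13.33					chr8:8061161-8061741/chr8:12318971-12319551
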