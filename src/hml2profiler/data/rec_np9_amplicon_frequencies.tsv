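# Relative cloning frequencies (%) and locus origins of rec/np9 amplicon cDNA sequences,
# from the same published survey. Frequencies are separated into np9-typical-length and
# rec-typical-length product classes (column prefix). The "ambiguous" row pools np9 cDNAs
# not assignable with certainty to reference or non-reference loci.
#total_sequences	np9|32-Mot=64	np9|35-Mot=19	np9|357-SC=17	np9|5847-SC=7	np9|802-SC=13	np9|5458-SC=24	rec|32-Mot=16	rec|35-Mot=18	rec|357-SC=21	rec|5847-SC=3	rec|802-SC=2	rec|23-Mot=3	rec|5458-SC=4
#condition	32-Mot=ALS	35-Mot=ALS	357-SC=ALS	5847-SC=ALS	802-SC=ALS	23-Mot=control	5458-SC=control
locus_id	np9|32-Mot	np9|35-Mot	np9|357-SC	np9|5847-SC	np9|802-SC	np9|5458-SC	rec|32-Mot	rec|35-Mot	rec|357-SC	rec|5847-SC	rec|802-SC	rec|23-Mot	rec|5458-SC	provirus_type	rec_np9	hg19_anchor
chr3q12.3_K-5	98	5	88	86	15	33	0	0	0	0	0	0	0	1	Np9	chr3:101412824
chr3q21.2_K-4	0	16	0	14	0	4	0	0	0	0	0	0	25	2	Rec	chr3:125611223
chr5q15_K-31	0	0	0	0	0	0	100	100	100	100	100	100	75	2		chr5:92793228
chr22q11.21_K-24	0	0	0	0	8	4	0	0	0	0	0	0	0	1	Np9	chr22:18934451
Venter	0	68	0	0	0	17	0	0	0	0	0	0	0	1
HERV-K111	2	11	0	0	46	17	0	0	0	0	0	0	0	1
ambiguous	0	0	12	0	31	25	0	0	0	0	0	0	0
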