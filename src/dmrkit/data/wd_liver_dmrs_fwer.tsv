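# Reference set: genome-wide-significant Wilson disease liver DMRs (hg38)
# with permutation FWER and nearest-gene annotations (distance in kb,
# negative = upstream of the TSS; position category relative to gene 1).
chrom	start	end	n_cpgs	meth_diff_pct	fwer	gene1	dist1_kb	pos1	gene2	dist2_kb	pos2
chr2	131557558	131560049	156	-37	<0.001	TIAM1	0.0	TSS	LOC150051	0.0	TSS
chr12	3199472	3201083	96	-35	0.004	TSPAN9	122.1	Intron	PRMT8	-180.3	Upstream
chr9	136050881	136052939	57	-35	0.008	NACC2	42.3	Intron	UBAC1	-89.5	Upstream
chr22	27797270	27798795	87	27	0.018	MN1	2.7	Exon	LOC100507657	486.6	Downstream
chr15	99105435	99106614	93	-13	0.020	SYNM	0.4	Exon	LRRC28	-144.7	Upstream
chr18	22171324	22172395	66	-27	0.023	GATA6-AS1	-2.4	Upstream
chr21	44456208	44457837	56	29	0.023	LRRC3	0.7	Exon	LRRC3-AS1	-0.9	Upstream
chr20	40691316	40693007	60	-28	0.025	MAFB	-2.1	Upstream
chr9	137461602	137462399	37	-28	0.028	NSMF	-2.3	Upstream
chr9	136418051	136418847	29	32	0.031	SDCCAG3	-7.4	Upstream	INPP5E	21.0	Downstream
chr11	66855700	66857160	56	-32	0.032	LRFN4	-0.2	Upstream
chr22	39994424	39995559	72	-24	0.035	FAM83F	0.0	TSS
chr4	15702770	15703332	32	-28	0.038	BST1	0.0	TSS
chr14	37597362	37599120	65	-17	0.038	FOXA1	-2.2	Upstream
chr16	30604376	30605260	48	29	0.043	ZNF689	5.5	Exon	ZNF785	-18.6	Upstream
chr17	28371994	28372583	59	-20	0.044	SARM1	0.3	Exon	VTN	-1.6	Upstream
chr9	121772727	121773248	32	23	0.048	DAB2IP	205.6	Exon	TTLL11	320.4	Downstream
chr5	10649279	10650004	64	18	0.049	ANKRD33B	85.0	Exon	DAP	111.3	Downstream
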