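gene_id	genomic_bp	n_introns	total_intron_bp	avg_intron_bp	n_exons	total_exon_bp	avg_exon_bp
MperOBP2	5836	4	5104	1276	5	732	146
MperOBP3	16810	5	16384	3277	6	426	71
MperOBP4	3269	6	2669	445	7	600	86
MperOBP5	10647	8	9981	1248	9	666	74
MperOBP6	5530	7	4882	697	8	648	81
MperOBP7	7442	6	6992	1165	7	450	64
MperOBP8	4849	6	4363	727	7	486	69
MperOBP9	5063	6	4562	760	7	501	72
MperOBP10	2851	6	2419	403	7	432	62
MperCSP1	11282	1	10424	10424	2	858	429
MperCSP2	1136	1	740	740	2	396	198
MperCSP4	1033	1	595	595	2	438	219
MperCSP5	1770	1	1350	1350	2	420	210
MperCSP6	1704	1	1308	1308	2	396	198
MperCSP7	8096	2	7628	3814	3	468	156
MperCSP8	3324	1	2832	2832	2	492	246
MperCSP9	2170	1	1681	1681	2	489	245
MperCSP10	3910	1	3457	3457	2	453	227
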