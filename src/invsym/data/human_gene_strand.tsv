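# Published counts of protein-coding and RNA genes on the plus (P) and
# minus (M) strands of HG38 chromosomes.
chrom	n_plus	n_minus
chr1	4488	4291
chr2	4106	3367
chr3	2938	2516
chr4	2542	1792
chr5	2777	2186
chr6	4840	3563
chr7	3024	2402
chr8	2135	2032
chr9	3022	2180
chr10	2532	2156
chr11	2879	4047
chr12	3003	2771
chr13	1261	1227
chr14	2092	1906
chr15	4226	3547
chr16	2529	1875
chr17	3582	2902
chr18	1182	1490
chr19	3287	3036
chr20	1258	1193
chr21	670	779
chr22	1429	1793
chrX	1927	1572
chrY	491	184
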