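# Published k-limits (k at which E_k[X] is closest to 0.1) versus sequence
# length, for chromosomes of several species and for sections of human
# chromosomes. Used to test the logarithmic KL-vs-length law offline.
label	length_bp	k_limit
HG38_chr1	230000000	10
HG18_chr1	225000000	10
chimpanzee_chr1	217000000	10
mouse_chr1	192000000	10
HG18_chrX	151000000	9
zebrafish_chr7	77000000	9
D_melanogaster_chr3R	28000000	9
C_elegans_chrV	21000000	9
HG18_chrY	26000000	8
human_section_10M	10000000	8
E_coli_K12	4600000	8
B_subtilis	4200000	8
human_section_5M	5000000	7
M_avium_paratuberculosis	4800000	7
P_furiosus	1910000	7
T_maritima	1860000	7
S_cerevisiae_chrIV	1530000	7
human_section_1M	1000000	6
human_section_100K	100000	5
human_section_50K	50000	4
human_section_10K	10000	3
human_section_5K	5000	2
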