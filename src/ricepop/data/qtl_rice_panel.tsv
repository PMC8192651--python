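name	trait	chrom	panels	start	end	n_sig_snps	min_p	n_genes
1_DI	Diameter_Internode	2	FP	6805273	6923410	3	3.12E-08	18
2_GL	Grain_Length	2	FP,Jap	15480976	16798043	27	2.69E-12	197
3_GL_jap	Grain_Length	2	Jap	35638527	35927940	4	3.16E-11	58
4_GW_jap	Grain_Width	3	Jap	3334516	3532506	3	5.26E-09	34
5_GS	Grain_Length	3	FP,Ind,Jap	16520656	16908475	30	9.26E-17	53
6_GS	Grain_Width	3	FP,Jap	17686248	20833777	355	2.02E-13	471
7_GL	Grain_Length	4	FP	12043539	13108767	14	5.51E-11	167
8_HD	Heading_Date	4	FP	16165354	16384087	4	1.72E-08	37
9_PL	Panicle_Length	5	FP	667557	767557	2	6.17E-08	20
10_GS	Grain_Width	5	FP,Ind	4802345	5383914	57	2.40E-11	75
11_GL	Grain_Length	6	FP,Ind	1561006	1664716	16	2.68E-10	17
12_GL	Grain_Length	6	FP,Ind	6680831	7190137	51	1.81E-14	78
13_GL	Grain_Length	6	FP	7453914	7553914	2	5.90E-08	13
14_PL	Panicle_Length	6	FP	20400110	20500110	2	2.72E-08	13
15_GL_jap	Grain_Length	7	Jap	11519294	12296525	3	5.76E-08	99
16_FP	Floret_Pubescence	8	FP	18004654	18104654	2	1.64E-08	17
17_FP	Floret_Pubescence	8	FP	26175268	26275268	2	6.06E-08	15
18_FP	Floret_Pubescence	9	FP	6656837	7940621	51	7.23E-12	168
19_HD	Heading_Date	9	FP	14067272	14807406	7	6.86E-09	115
20_GW_jap	Grain_Width	10	Jap	1098998	1404807	6	3.61E-12	52
21_LW	Leaf_width	12	FP	17445137	17561823	2	2.14E-09	13
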