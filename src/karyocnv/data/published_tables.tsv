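key	description	a	b	c	d	published_or	published_p_two	pinned_cross_product
turner_45x_female_cases_vs_population	45,X carriers among female cases vs live-born female population sample	3	2194	3	17035	7.76	0.023	1
xxy_male_cases_vs_population	47,XXY carriers among male cases vs live-born male population sample	2	907	20	17852	NA	NA	0
large_all_cases_vs_screened	samples with >1 Mb CNVs, cases vs screened controls	74	2649	4	344	2.40	0.10	1
large_all_cases_vs_wtccc2	samples with >1 Mb CNVs, cases vs WTCCC2 controls	74	2649	45	2314	1.44	0.063	1
large_del_cases_vs_screened	samples with >1 Mb deletions, cases vs screened controls	20	2703	2	346	1.28	1.00	1
large_del_cases_vs_wtccc2	samples with >1 Mb deletions, cases vs WTCCC2 controls	20	2703	13	2346	1.34	0.49	1
large_dup_cases_vs_screened	samples with >1 Mb duplications, cases vs screened controls	54	2669	2	346	3.46	0.084	0
large_dup_cases_vs_wtccc2	samples with >1 Mb duplications, cases vs WTCCC2 controls	54	2669	32	2327	1.45	0.10	0
psychotic_all_vs_screened	samples with >1 Mb CNVs, psychotic-feature cases vs screened controls	5	136	4	344	3.16	0.13	1
psychotic_del_vs_screened	samples with >1 Mb deletions, psychotic-feature cases vs screened controls	0	141	2	346	0	0.51	1
psychotic_dup_vs_screened	samples with >1 Mb duplications, psychotic-feature cases vs screened controls	5	136	2	346	6.36	0.023	1
upd_cases_vs_wtccc2	whole-chromosome UPD carriers, cases vs WTCCC2 controls	3	3103	2	2697	1.30	1.00	1
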