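no	pathway	hits	total	raw_p	neg_log_p	impact
1	Aminoacyl-tRNA biosynthesis	8	67	5.3584e-07	14.439	0.0
2	d-Glutamine and d-glutamate metabolism	2	5	0.0015226	6.4874	0.0
3	Glycolysis/gluconeogenesis	3	26	0.0038445	5.5611	0.02862
4	Glycine, serine and threonine metabolism	3	32	0.0069872	4.9637	0.0
5	Valine, leucine and isoleucine biosynthesis	2	11	0.0079994	4.8284	0.66666
6	Arginine and proline metabolism	3	44	0.016934	4.0784	0.09426
7	Pyruvate metabolism	2	22	0.030903	3.4769	0.05583
8	Alanine, aspartate and glutamate metabolism	2	24	0.036368	3.3141	0.14979
9	Ubiquinone and other terpenoid-quinone biosynthesis	1	3	0.038051	3.2688	0.0
10	Galactose metabolism	2	26	0.042181	3.2688	0.0
11	Phenylalanine, tyrosine and tryptophan biosynthesis	1	4	0.050428	2.9872	0.5
12	Valine, leucine and isoleucine degradation	2	38	0.083347	2.4847	0.0
13	Taurine and hypotaurine metabolism	1	8	0.098447	2.3182	0.42857
14	Ascorbate and aldarate metabolism	1	9	0.11009	2.2065	0.0
15	Phenylalanine metabolism	1	9	0.11009	2.2065	0.0
16	Nitrogen metabolism	1	9	0.11009	2.2065	0.0
17	Selenoamino acid metabolism	1	15	0.17701	1.7316	0.0
18	Pantothenate and CoA biosynthesis	1	15	0.17701	1.7316	0.0
19	Glycerolipid metabolism	1	18	0.20866	1.5671	0.28098
20	Pentose phosphate pathway	1	19	0.21895	1.5189	0.0
21	Starch and sucrose metabolism	1	23	0.25887	1.3514	0.0021
22	Inositol phosphate metabolism	1	26	0.28753	1.2464	0.09464
23	Cysteine and methionine metabolism	1	28	0.30606	1.184	0.09464
24	Pyrimidine metabolism	1	41	0.41583	0.87749	0.0
25	Tyrosine metabolism	1	42	0.41583	0.85908	0.14045
26	Primary bile acid biosynthesis	1	46	0.4535	0.79076	0.02976
27	Purine metabolism	1	68	0.59365	0.52147	0.0
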