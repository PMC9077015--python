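metabolite	shifts	dir_model_vs_control	stars_model_vs_control	dir_treated_vs_model	stars_treated_vs_model
HDL	0.84 (m)	none	ns	none	ns
Lipids	0.89 (m), 1.29 (m)	up	**	down	**
Leucine	0.95 (d)	none	ns	up	**
Valine	0.97 (d), 1.02 (d)	down	*	up	**
Lactate	1.33 (d), 4.11 (t)	none	ns	up	**
Alanine	1.48 (d)	none	ns	up	**
Arginine	1.68 (m)	down	*	up	**
Acetate	1.91 (s)	none	ns	up	**
N-Acetyl glycoprotein	2.04 (s)	up	**	none	ns
Methionine	2.13 (s)	none	ns	up	**
Glutamate	2.14 (m)	down	**	up	**
Glutamine	2.41 (m)	down	*	up	**
Creatine	3.04 (s)	down	*	up	**
Taurine	3.25 (t), 3.41 (t)	down	*	up	*
Threonine	3.56 (dd)	down	*	up	**
Myo-inositol	3.63 (dd)	down	*	up	**
Glycerol	3.64 (dd), 3.87 (m)	down	*	up	**
TMAO/Betaine	3.27 (s)	down	**	up	**
Tyrosine	6.87 (m), 7.17 (m)	down	*	up	**
beta-Glucose	4.64 (d)	down	**	up	**
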