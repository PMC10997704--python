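id	name	reference_rt_min	w428	w478	w519
1	emodin-1,6-di-glycoside	2.2	0.60	0.30	0.10
2	dermolutein-1,6-di-glycoside	3.4	0.70	0.20	0.10
3	endocrocin-1,6-di-glycoside	4.6	0.70	0.20	0.10
4	dermolutein-6-glycoside	5.8	0.70	0.20	0.10
5	endocrocin-6-glycoside	7.0	0.70	0.20	0.10
6	emodin-1-glycoside	8.2	0.60	0.30	0.10
7	dermocybin-1-glycoside	9.4	0.20	0.30	0.50
8	dermolutein	10.6	0.70	0.20	0.10
9	dermorubin	11.8	0.20	0.30	0.50
10	endocrocin	13.0	0.70	0.20	0.10
11	flavomannin-6,6'-dimethyl-ether (FDM)	14.2	0.80	0.15	0.05
12	emodin	15.4	0.60	0.30	0.10
13	dermocybin	16.6	0.15	0.30	0.55
14	anhydroflavomannin-9,10-chinon-6,6'-dimethylether (AFDM)	17.8	0.75	0.20	0.05
15	7,7'-biphyscion	19.0	0.60	0.30	0.10
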