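name	p_value	fold_change
Xanthurenic acid	3.93E-06	26.18
Guanine	0.000	7.75
Pyrrole-2-carboxylic acid	0.040	3.33
Uric acid	1.19E-07	3.19
Melezitose	0.010	3.08
Malate	1.86E-05	2.94
2-Hydroxypyridine	4.14E-05	2.67
3-Hydroxypropionic acid	0.002	2.02
Glyceric acid	0.000	2.01
4-Hydroxybenzoic acid	9.56E-05	1.98
Citric acid	0.041	1.87
Glycolic acid	0.032	1.78
Glucose-6-phosphate	0.036	1.77
Sucrose	0.004	1.75
Fumaric acid	0.005	1.71
Tagatose	0.001	1.57
Xylose	0.002	1.45
Stearic acid	0.020	1.45
Gamma-aminobutyric acid	0.001	1.44
Myo-inositol	0.003	1.42
Fructose	0.034	1.36
3,6-Anhydro-D-galactose	0.000	1.36
Lauric acid	0.000	1.28
Oleic acid	0.036	1.26
Arachidic acid	0.006	1.24
Lysine	0.012	1.22
Serine	0.001	1.16
1-Monopalmitin	0.020	1.16
Palmitoleic acid	0.008	1.10
O-Phosphorylethanolamine	0.014	1.08
Glycine	0.005	0.91
Ornithine	0.019	0.86
Lactic acid	0.001	0.83
Inosine	0.000	0.83
Lignoceric acid	0.026	0.74
Ethanolamine	0.006	0.73
L-Homoserine	1.96E-05	0.68
Threose	0.000	0.62
5'-Deoxy-5'-methylthioadenosine	3.86E-06	0.60
L-Cysteine	5.37E-06	0.50
Galactonic acid	0.022	0.48
Methionine sulfoxide	0.000	0.46
Lactose	0.038	0.46
Gluconic acid lactone	0.029	0.44
Arabitol	0.005	0.18
Methionine	2.1E-08	0.15
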