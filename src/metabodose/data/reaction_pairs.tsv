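Methionine	5'-Deoxy-5'-methylthioadenosine
Methionine	Methionine sulfoxide
L-Homoserine	Methionine
Serine	Glycine
Glycine	Serine
L-Cysteine	Serine
Fumaric acid	Malate
Glucose-6-phosphate	Fructose
Lactic acid	Pyruvate
Ornithine	Putrescine
Ethanolamine	O-Phosphorylethanolamine
Gluconic acid lactone	Glucose-6-phosphate
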