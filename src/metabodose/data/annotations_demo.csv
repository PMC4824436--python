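name,compound_id,smiles,fingerprint,pathway_tag
Xanthurenic acid,5699,OC(=O)c1cc(O)c2cccc(O)c2n1,,tryptophan/ommochrome
Guanine,135398634,Nc1nc2[nH]cnc2c(=O)[nH]1,,purine
Pyrrole-2-carboxylic acid,,OC(=O)c1ccc[nH]1,,sialic acid degradation
Uric acid,1175,O=C1NC(=O)c2[nH]c(=O)[nH]c2N1,,purine
Melezitose,,,,carbohydrate
Malate,525,OC(CC(=O)O)C(=O)O,,TCA
2-Hydroxypyridine,,Oc1ccccn1,,other
3-Hydroxypropionic acid,,OCCC(=O)O,,organic acid
Glyceric acid,,OCC(O)C(=O)O,,glycolysis-adjacent
4-Hydroxybenzoic acid,135,Oc1ccc(cc1)C(=O)O,,aromatic acid
Citric acid,311,OC(=O)CC(O)(C(=O)O)CC(=O)O,,TCA
Glycolic acid,757,OCC(=O)O,,organic acid
Glucose-6-phosphate,,OC1OC(COP(=O)(O)O)C(O)C(O)C1O,,glycolysis
Sucrose,5988,OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O,,carbohydrate
Fumaric acid,444972,OC(=O)/C=C/C(=O)O,,TCA
Tagatose,,OCC(O)C(O)C(O)C(=O)CO,,carbohydrate
Xylose,,OCC(O)C(O)C(O)C=O,,pentose
Stearic acid,5281,CCCCCCCCCCCCCCCCCC(=O)O,,fatty acid
Gamma-aminobutyric acid,119,NCCCC(=O)O,,amino acid derived
Myo-inositol,892,OC1C(O)C(O)C(O)C(O)C1O,,polyol
Fructose,,OCC(O)C(O)C(O)C(=O)CO,,carbohydrate
"3,6-Anhydro-D-galactose",,,,carbohydrate
Lauric acid,3893,CCCCCCCCCCCC(=O)O,,fatty acid
Oleic acid,445639,CCCCCCCC/C=C\CCCCCCCC(=O)O,,fatty acid
Arachidic acid,10467,CCCCCCCCCCCCCCCCCCCC(=O)O,,fatty acid
Lysine,5962,NCCCCC(N)C(=O)O,,amino acid
Serine,5951,OCC(N)C(=O)O,,amino acid
1-Monopalmitin,,CCCCCCCCCCCCCCCC(=O)OCC(O)CO,,neutral lipid
Palmitoleic acid,445638,CCCCCC/C=C\CCCCCCCC(=O)O,,fatty acid
O-Phosphorylethanolamine,1015,NCCOP(=O)(O)O,,phospholipid headgroup
Glycine,750,NCC(=O)O,,amino acid
Ornithine,6262,NCCCC(N)C(=O)O,,polyamine pathway
Lactic acid,612,CC(O)C(=O)O,,glycolysis
Inosine,6021,OCC1OC(n2cnc3c2N=CNC3=O)C(O)C1O,,purine
Lignoceric acid,11197,CCCCCCCCCCCCCCCCCCCCCCCC(=O)O,,very long chain fatty acid
Ethanolamine,700,NCCO,,phospholipid headgroup
L-Homoserine,12647,OCCC(N)C(=O)O,,methionine pathway
Threose,,OCC(O)C(O)C=O,,carbohydrate
5'-Deoxy-5'-methylthioadenosine,439176,CSCC1OC(n2cnc3c(N)ncnc32)C(O)C1O,,methionine salvage
L-Cysteine,5862,NC(CS)C(=O)O,,sulfur amino acid
Galactonic acid,,OCC(O)C(O)C(O)C(O)C(=O)O,,carbohydrate
Methionine sulfoxide,847,CS(=O)CCC(N)C(=O)O,,sulfur amino acid
Lactose,6134,OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1O,,carbohydrate
Gluconic acid lactone,7027,OCC1OC(=O)C(O)C(O)C1O,,pentose phosphate entry
Arabitol,,OCC(O)C(O)C(O)CO,,polyol
Methionine,6137,CSCCC(N)C(=O)O,,methionine salvage
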