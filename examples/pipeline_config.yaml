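# Full-pipeline configuration for `metabodose run --config pipeline_config.yaml`
# Generate the inputs first:
#   metabodose simulate --seed 1 --out table.csv --truth truth.json
abundance_path: table.csv
genotype_map_path: table.genotypes.csv
# annotation_path: annotations.csv        # optional: enables the similarity layer
# reaction_pairs_path: reaction_pairs.tsv # optional: enables the reaction layer
out_dir: pipeline_out
alpha: 0.05
presence_fraction: 0.8
tic_rescale: mean          # or "none" for pure fractions
tanimoto_threshold: 0.7
pca_scaling: autoscale     # or "center" for covariance PCA
welch: false               # pooled-variance Student's t by default
dosage_order: [WT, het, hom]
template_down: [1.0, 0.5, 0.0]
template_up: [0.0, 0.5, 1.0]
ptm_threshold: 0.05
comparisons:
  - [hom_vs_wt, hom, WT]
  - [gal4_vs_wt, gal4, WT]
  - [gal4_vs_rescue, gal4, rescue]
  - [hom_vs_gal4, hom, gal4]
seed: 1
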