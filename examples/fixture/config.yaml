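layers:
- layer: colon_transcriptome
  level: gene
  table_path: colon_transcriptome_gene.tsv
- layer: colonic_microbiome
  level: genus
  table_path: colonic_microbiome_genus.tsv
- layer: lung_transcriptome
  level: gene
  table_path: lung_transcriptome_gene.tsv
- layer: muscle_metabolome
  level: metabolite
  table_path: muscle_metabolome_metabolite.tsv
- layer: nasal_microbiome
  level: genus
  table_path: nasal_microbiome_genus.tsv
metadata_path: metadata.tsv
outdir: fixture_out
seed: 42
group_filter: high
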