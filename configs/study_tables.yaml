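# Column mappings and defaults for the packaged study tables.
groups: [cyto_mito, syncytio_mito]
pseudocount: 1
alpha: 0.05
min_unique_peptides: 3
unchanged_tolerance: 0
background_mode: column_totals
compute_q_values: false
stage_pseudocounts:
  first_trimester: 0
  third_trimester: 1
count_columns:
  protein_id: "Protein ID"
  gene: "Gene name"
  groups:
    cyto_mito: "Average unique peptides Cyto-Mito"
    syncytio_mito: "Average unique peptides Syncytio-Mito"
expression_columns:
  gene: Gene
  tpm:
    cytotrophoblast: CYT
    syncytiotrophoblast: SYN
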