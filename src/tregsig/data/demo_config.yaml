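# Demo pipeline configuration: two synthetic single-cell cohorts sharing 15
# planted Treg-restricted DE genes, a primary survival cohort with 6 of those
# genes prognostic (log-hazard ln 2 per z-unit), one secondary cohort with the
# same signal and one null cohort.  Runs end-to-end in about a minute on one CPU.
seed: 17
outdir: runs/demo
sc_cohorts:
  ccrcc:
    n_genes: 300
    lineages:
      Treg: {PB: 120, TI: 150}
      CD4conv: {PB: 80, TI: 80}
      CD8: {PB: 80, TI: 80}
      NK: {PB: 60, TI: 60}
      B: {PB: 60, TI: 60}
      myeloid: {PB: 60, TI: 60}
    planted_de:
      - [0, 4.86, 0.202, 0.0]
      - [1, 3.5, 0.6, 0.1]
      - [2, 3.0, 0.55, 0.12]
      - [3, 2.8, 0.5, 0.1]
      - [4, 2.6, 0.5, 0.15]
      - [5, 2.5, 0.45, 0.1]
      - [6, 2.4, 0.5, 0.2]
      - [7, 2.3, 0.45, 0.15]
      - [8, 2.2, 0.4, 0.1]
      - [9, 2.1, 0.45, 0.18]
      - [10, 2.0, 0.4, 0.12]
      - [11, 1.9, 0.4, 0.15]
      - [12, 1.8, 0.35, 0.1]
      - [13, 1.7, 0.4, 0.18]
      - [14, 1.6, 0.35, 0.12]
  hcc:
    n_genes: 300
    lineages:
      Treg: {PB: 100, TI: 130}
      CD4conv: {PB: 70, TI: 70}
      CD8: {PB: 70, TI: 70}
      NK: {PB: 50, TI: 50}
      B: {PB: 50, TI: 50}
      myeloid: {PB: 50, TI: 50}
    planted_de:
      - [0, 4.55, 0.25, 0.0]
      - [1, 3.2, 0.55, 0.1]
      - [2, 2.9, 0.5, 0.1]
      - [3, 2.7, 0.5, 0.12]
      - [4, 2.5, 0.45, 0.12]
      - [5, 2.4, 0.45, 0.1]
      - [6, 2.3, 0.5, 0.2]
      - [7, 2.2, 0.45, 0.15]
      - [8, 2.1, 0.4, 0.1]
      - [9, 2.0, 0.4, 0.15]
      - [10, 1.9, 0.4, 0.12]
      - [11, 1.8, 0.4, 0.15]
      - [12, 1.7, 0.35, 0.1]
      - [13, 1.6, 0.35, 0.15]
      - [14, 1.5, 0.35, 0.12]
qc: {min_genes: 20, max_genes: 300}
deg_filter: {min_logfc: 1.0, max_padj: 0.05, min_delta_pct: 0.0}
specificity:
  target_lineage: Treg
  other_lineages: [CD4conv, CD8, NK, B, myeloid]
  min_logfc: 1.0
  max_fdr: 0.05
  min_comparisons: 3
survival_cohorts:
  kirc:
    n_samples: 533
    n_genes: 300
    planted_prognostic:
      - [0, 0.693]
      - [1, 0.693]
      - [2, 0.693]
      - [3, 0.693]
      - [4, 0.693]
      - [5, 0.693]
    baseline_hazard: 0.1
    censoring_hazard: 0.05
  lihc:
    n_samples: 300
    n_genes: 300
    planted_prognostic:
      - [0, 0.693]
      - [1, 0.693]
      - [2, 0.693]
      - [3, 0.693]
      - [4, 0.693]
      - [5, 0.693]
    baseline_hazard: 0.12
    censoring_hazard: 0.05
  nullcohort:
    n_samples: 300
    n_genes: 300
    baseline_hazard: 0.1
    censoring_hazard: 0.05
primary_cohort: kirc
ensemble: {rounds: 60, max_group_size: 15, subset_size: 5, signature_size: 6}
split: {train_fraction: 0.10}
grade_stratify: 3
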