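# Small end-to-end demo: three repeat families (dispersed gene-poor-seeking,
# dispersed gene-rich-seeking, single-locus tandem) in a two-population design.
seed: 11
outdir: runs/demo

simulate:
  families:
    - {name: gypA, class_label: Gypsy-like, monomer_length: 600, copies: 40, divergence: 0.03, bias: -0.8}
    - {name: copB, class_label: Copia-like, monomer_length: 500, copies: 40, divergence: 0.03, bias: 0.8}
    - {name: tanC, class_label: tandem, monomer_length: 180, copies: 120, divergence: 0.01}
  chrom_lengths: {chr1: 400000, chr2: 300000}
  n_genes_per_chrom: 40
  gene_length: 2000
  population:
    n_individuals_per_pop: 4
    pop_labels: [SS, NSS]
    snp_count: 60
    snp_divergence: 0.2
    heterozygosity_rate: 0.0
    repeat_effect: 1.0
  reads_per_individual: 120
  read_length: 150

similarity:
  min_report_bits: 100.0
  seed_length: 16

cluster:
  min_bits: 100.0
  weighted: true
  largest_component_only: false
  n_layout_clusters: 2

annotate:
  min_bits: 50.0

diff:
  alpha: 0.05

paint:
  k: 12
  top: 100
  window: 200000
  step: 100000
  span: 0.1
  n_clusters: 3

plots: false
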