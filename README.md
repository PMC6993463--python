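# repeatpop

Reference-free repeat profiling from skim sequencing. `repeatpop` pools
low-coverage shotgun reads from many individuals, builds a bit-score-weighted
read-similarity graph, detects repeat families as graph communities, tests
per-family abundance differences between two populations, paints each
family's chromosomal distribution with its most abundant 12-mers, correlates
that distribution with gene density, and contrasts population structure
inferred from repeat abundances against SNP genotypes. A first-class
synthetic-data module generates repeat libraries, annotated genomes,
structured populations, and reads with known ground truth, so every stage is
testable end to end without external downloads.

## Pipeline stages

| stage        | what it does |
|--------------|--------------|
| `simulate`   | repeat library, genome (genes + planted repeat copies with placement bias), two-population copy-number/SNP tables, shotgun reads |
| `similarity` | all-vs-all seeded ungapped read scoring in Karlin–Altschul bits (or import of BLAST outfmt-6 hits) |
| `cluster`    | similarity graph (edges ≥ 100 bits), greedy-modularity repeat clusters, per-individual abundance matrix, cluster meta-graph, Fruchterman–Reingold layouts |
| `annotate`   | majority best-hit cluster annotation against a labelled repeat library |
| `diff`       | two-sided t-tests per cluster / per annotation class with Benjamini–Hochberg correction |
| `paint`      | top-100 canonical 12-mers per cluster mapped exactly to a genome, 200 kb / 100 kb sliding-window densities, min/max scaling, loess smoothing, Pearson/Spearman correlation with gene density |
| `structure`  | min/max-scaled repeat PCA vs encoded SNP PCA (major=1, minor=0, heterozygotes masked), silhouette-based group separation |

## CLI

Every stage is a subcommand of `repeatpop`; `run` executes a YAML-configured
end-to-end pipeline and writes a manifest with parameters and output
checksums. Runs are deterministic per seed.

```bash
repeatpop run --config examples/demo.yaml --seed 11 --outdir runs/demo
repeatpop simulate  --config examples/demo.yaml --seed 11 --outdir runs/sim
repeatpop similarity --reads-dir runs/sim/reads --out runs/sim/hits.tsv
repeatpop cluster   --hits runs/sim/hits.tsv --reads-dir runs/sim/reads --out runs/sim
repeatpop annotate  --assignment runs/sim/assignment.tsv --reads-dir runs/sim/reads \
                    --library runs/sim/library.fa --out runs/sim/annotation.tsv
repeatpop diff      --matrix runs/sim/abundance.tsv --labels runs/sim/labels.tsv \
                    --out runs/sim/diff.tsv
repeatpop paint     --assignment runs/sim/assignment.tsv --reads-dir runs/sim/reads \
                    --genome runs/sim/genome.fa --genes runs/sim/genes.bed --out runs/sim/paint
repeatpop structure --matrix runs/sim/abundance.tsv --genotypes runs/sim/genotypes.tsv \
                    --labels runs/sim/labels.tsv --out runs/sim/structure
```

See `examples/demo.yaml` for the configuration schema. External BLAST hits
can replace the internal scorer via `repeatpop similarity --import blast.tsv`
(outfmt 6). Genotypes may be a TSV of allele-pair calls or a plain-text VCF.

## Conventions

- All internal coordinates are 0-based, half-open; GFF3 is converted at the
  I/O boundary.
- Mutation model is substitution-only, so read lengths and k-mer arithmetic
  stay exact.
- Every generator and stage derives its random stream from the run seed and
  the stage name; identical configs give byte-identical outputs.
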