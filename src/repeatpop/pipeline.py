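"""End-to-end pipeline orchestration with a run manifest.

Stages run in order: simulate -> similarity -> cluster -> annotate -> diff
-> paint -> structure. Every stage derives its random stream from the run
seed and the stage name, so re-running a config reproduces its outputs
byte for byte. The manifest records package version, full configuration,
and checksums of the files each stage wrote.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__, io
from .annotate import annotate_clusters, aggregate_by_annotation
from .graph import (
    abundance_matrix,
    build_graph,
    cluster_metagraph,
    detect_communities,
    layout_cluster,
    mean_degree,
)
from .paint import paint_cluster
from .similarity import DEFAULT_PARAMS, ScoringParams, all_vs_all
from .simulate import (
    PopulationConfig,
    ReadSet,
    RepeatFamilySpec,
    build_genome,
    make_repeat_library,
    shotgun_reads,
    simulate_population,
)
from .stats import differential_abundance
from .structure import structure_contrast

logger = logging.getLogger(__name__)

DEFAULT_STAGES = (
    "simulate",
    "similarity",
    "cluster",
    "annotate",
    "diff",
    "paint",
    "structure",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing input {path}")
    return path


def _family_specs(cfg: list[dict]) -> list[RepeatFamilySpec]:
    return [
        RepeatFamilySpec(
            name=f["name"],
            class_label=f.get("class_label", "other"),
            monomer_length=int(f.get("monomer_length", 500)),
            target_copy_number=int(f.get("copies", 50)),
            intra_family_divergence=float(f.get("divergence", 0.03)),
            placement_bias=float(f.get("bias", 0.0)),
        )
        for f in cfg
    ]


def _scoring_params(cfg: dict) -> ScoringParams:
    return replace(
        DEFAULT_PARAMS,
        **{
            key: cfg[key]
            for key in (
                "match",
                "mismatch",
                "seed_length",
                "lam",
                "k_const",
                "min_report_bits",
            )
            if key in cfg
        },
    )


def run_pipeline(config: dict[str, Any]) -> Path:
    """Execute the configured stages; returns the run directory."""
    outdir = Path(config.get("outdir", "repeatpop_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": stages,
        "outputs": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["outputs"].setdefault(stage, {})
        for p in paths:
            manifest["outputs"][stage][p.name] = io.file_sha256(p)

    reads: ReadSet | None = None
    if "simulate" in stages:
        try:
            sim = config.get("simulate", {})
            specs = _family_specs(sim.get("families", []))
            if not specs:
                raise ValueError("simulate.families is empty")
            library = make_repeat_library(specs, seed)
            chrom_lengths = {
                str(k): int(v) for k, v in sim.get("chrom_lengths", {"chr1": 300_000}).items()
            }
            genome = build_genome(
                library,
                None,
                chrom_lengths,
                seed,
                n_genes_per_chrom=int(sim.get("n_genes_per_chrom", 40)),
                gene_length=int(sim.get("gene_length", 2000)),
            )
            pop_cfg = sim.get("population", {})
            pconfig = PopulationConfig(
                n_individuals_per_pop=int(pop_cfg.get("n_individuals_per_pop", 4)),
                pop_labels=tuple(pop_cfg.get("pop_labels", ("SS", "NSS"))),
                snp_count=int(pop_cfg.get("snp_count", 100)),
                snp_divergence=float(pop_cfg.get("snp_divergence", 0.2)),
                repeat_effect=pop_cfg.get("repeat_effect", 1.0),
                heterozygosity_rate=float(pop_cfg.get("heterozygosity_rate", 0.0)),
                seed=seed,
            )
            copy_df, geno_df, labels = simulate_population(genome, pconfig)
            n_reads = int(sim.get("reads_per_individual", 200))
            read_length = int(sim.get("read_length", 150))
            reads = ReadSet()
            reads_dir = outdir / "reads"
            reads_dir.mkdir(exist_ok=True)
            for i, ind in enumerate(copy_df.index):
                rs = shotgun_reads(
                    genome,
                    n_reads,
                    read_length,
                    seed + 1000 + i,
                    individual=ind,
                    population=labels[ind],
                )
                io.write_reads_fasta(rs, reads_dir / f"{ind}.fa")
                reads.extend(rs)
            io.write_library_fasta(library, outdir / "library.fa")
            io.write_genome_fasta(genome, outdir / "genome.fa")
            io.write_bed(
                ((c, s, e, f"gene_{i}", 0, "+") for i, (c, s, e) in enumerate(genome.genes)),
                outdir / "genes.bed",
            )
            io.write_truth_bed(genome, outdir / "truth.bed")
            io.write_tsv_matrix(copy_df, outdir / "copy_numbers.tsv")
            io.write_tsv_matrix(geno_df, outdir / "genotypes.tsv")
            labels.to_frame().to_csv(outdir / "labels.tsv", sep="\t", index_label="id")
            record(
                "simulate",
                outdir / "library.fa",
                outdir / "genome.fa",
                outdir / "genes.bed",
                outdir / "truth.bed",
                outdir / "copy_numbers.tsv",
                outdir / "genotypes.tsv",
                outdir / "labels.tsv",
            )
        except (ValueError, KeyError) as exc:
            raise StageError("simulate", str(exc)) from exc

    params = _scoring_params(config.get("similarity", {}))
    if "similarity" in stages:
        try:
            if reads is None:
                reads_dir = _require(outdir / "reads", "similarity")
                reads = ReadSet()
                for fa in sorted(reads_dir.glob("*.fa")):
                    reads.extend(io.read_reads_fasta(fa))
            import_path = config.get("similarity", {}).get("import_hits")
            if import_path:
                hits = io.read_hits_tsv(_require(Path(import_path), "similarity"))
            else:
                hits = all_vs_all(reads, params)
            io.write_hits_tsv(hits, outdir / "hits.tsv")
            record("similarity", outdir / "hits.tsv")
        except (ValueError, KeyError) as exc:
            raise StageError("similarity", str(exc)) from exc

    assignment = None
    g = None
    abundance = None
    pops = None
    if "cluster" in stages:
        try:
            if reads is None:
                reads_dir = _require(outdir / "reads", "cluster")
                reads = ReadSet()
                for fa in sorted(reads_dir.glob("*.fa")):
                    reads.extend(io.read_reads_fasta(fa))
            hits = io.read_hits_tsv(_require(outdir / "hits.tsv", "cluster"))
            ccfg = config.get("cluster", {})
            min_bits = float(ccfg.get("min_bits", 100.0))
            labels_map = reads.labels()
            g = build_graph(hits, labels_map, min_bits=min_bits)
            stats_path = outdir / "graph_stats.json"
            io.write_manifest(
                {
                    "n_vertices": g.number_of_nodes(),
                    "n_edges": g.number_of_edges(),
                    "mean_degree": mean_degree(g.number_of_nodes(), g.number_of_edges()),
                    "n_unclustered_reads": len(reads) - g.number_of_nodes(),
                },
                stats_path,
            )
            if ccfg.get("largest_component_only", False):
                from .graph import largest_component

                g = largest_component(g)
            assignment = detect_communities(g, weighted=bool(ccfg.get("weighted", True)))
            with open(outdir / "assignment.tsv", "w") as fh:
                fh.write("read_id\tcluster_id\tindividual\tpopulation\n")
                for cid, members in enumerate(assignment.clusters):
                    for rid in members:
                        ind, pop = labels_map[rid]
                        fh.write(f"{rid}\tcluster_{cid}\t{ind}\t{pop}\n")
            abundance, pops = abundance_matrix(assignment, labels_map)
            io.write_tsv_matrix(abundance, outdir / "abundance.tsv")
            meta = cluster_metagraph(g, assignment)
            with open(outdir / "metagraph.tsv", "w") as fh:
                fh.write("cluster_a\tcluster_b\tweight\n")
                for a, b, data in sorted(meta.edges(data=True)):
                    fh.write(f"cluster_{a}\tcluster_{b}\t{data['weight']:g}\n")
            n_layout = int(ccfg.get("n_layout_clusters", 0))
            if n_layout:
                with open(outdir / "layouts.tsv", "w") as fh:
                    fh.write("cluster_id\tread_id\tx\ty\n")
                    for cid in range(min(n_layout, len(assignment))):
                        for rid, (x, y) in layout_cluster(
                            g, assignment, cid, seed=seed
                        ).items():
                            fh.write(f"cluster_{cid}\t{rid}\t{x:.6f}\t{y:.6f}\n")
            record(
                "cluster",
                outdir / "assignment.tsv",
                outdir / "abundance.tsv",
                outdir / "metagraph.tsv",
                stats_path,
            )
        except (ValueError, KeyError) as exc:
            raise StageError("cluster", str(exc)) from exc

    annotations = None
    if "annotate" in stages:
        try:
            if assignment is None or reads is None:
                raise StageError("annotate", "cluster stage must run first")
            library = io.read_library_fasta(_require(outdir / "library.fa", "annotate"))
            acfg = config.get("annotate", {})
            aparams = replace(
                params, min_report_bits=float(acfg.get("min_bits", 50.0))
            )
            read_by_id = {r.id: r for r in reads}
            cluster_reads = [
                ReadSet(read_by_id[rid] for rid in members)
                for members in assignment.clusters
            ]
            annotations = annotate_clusters(cluster_reads, library, aparams)
            io.write_annotation_tsv(annotations, outdir / "annotation.tsv")
            if abundance is not None:
                class_ab = aggregate_by_annotation(abundance, annotations)
                io.write_tsv_matrix(class_ab, outdir / "class_abundance.tsv")
                record("annotate", outdir / "annotation.tsv", outdir / "class_abundance.tsv")
            else:
                record("annotate", outdir / "annotation.tsv")
        except (ValueError, KeyError) as exc:
            raise StageError("annotate", str(exc)) from exc

    if "diff" in stages:
        try:
            dcfg = config.get("diff", {})
            alpha = float(dcfg.get("alpha", 0.05))
            if abundance is None:
                abundance = io.read_tsv_matrix(_require(outdir / "abundance.tsv", "diff"))
            if pops is None:
                lab_df = pd.read_csv(
                    _require(outdir / "labels.tsv", "diff"), sep="\t", index_col=0
                )
                pops = lab_df["population"]
            written = []
            if abundance.shape[0] >= 4:
                diff = differential_abundance(abundance, pops, alpha=alpha)
                diff.to_csv(outdir / "diff_clusters.tsv", sep="\t")
                written.append(outdir / "diff_clusters.tsv")
            class_path = outdir / "class_abundance.tsv"
            if class_path.exists():
                class_ab = io.read_tsv_matrix(class_path)
                diff_c = differential_abundance(class_ab, pops, alpha=alpha)
                diff_c.to_csv(outdir / "diff_classes.tsv", sep="\t")
                written.append(outdir / "diff_classes.tsv")
            record("diff", *written)
        except (ValueError, KeyError) as exc:
            raise StageError("diff", str(exc)) from exc

    if "paint" in stages:
        try:
            pcfg = config.get("paint", {})
            genome_path = Path(pcfg.get("genome", outdir / "genome.fa"))
            genes_path = Path(pcfg.get("genes", outdir / "genes.bed"))
            genome_seqs = io.read_genome_fasta(_require(genome_path, "paint"))
            genes = [
                (chrom, s, e) for chrom, s, e, _, _ in io.read_bed(
                    _require(genes_path, "paint")
                )
            ]
            if assignment is None or reads is None:
                raise StageError("paint", "cluster stage must run first")
            read_by_id = {r.id: r for r in reads}
            n_paint = int(pcfg.get("n_clusters", 3))
            corr_rows = []
            track_rows = []
            for cid in range(min(n_paint, len(assignment))):
                members = assignment.clusters[cid]
                cluster_reads = ReadSet(read_by_id[rid] for rid in members)
                result = paint_cluster(
                    cluster_reads,
                    genome_seqs,
                    genes,
                    cluster_id=cid,
                    k=int(pcfg.get("k", 12)),
                    top=int(pcfg.get("top", 100)),
                    width=int(pcfg.get("window", 200_000)),
                    step=int(pcfg.get("step", 100_000)),
                    span=float(pcfg.get("span", 0.1)),
                )
                c = result.correlation
                corr_rows.append(
                    {
                        "cluster": f"cluster_{cid}",
                        "genome": c.genome_id,
                        "pearson_r": c.pearson_r,
                        "pearson_p": c.pearson_p,
                        "spearman_rho": c.spearman_rho,
                        "spearman_p": c.spearman_p,
                        "n_windows": c.n_windows,
                        "defined": c.defined,
                    }
                )
                for chrom, track in result.tracks.items():
                    for (ws, we), raw, scl, smo, gd in zip(
                        track.windows, track.raw, track.scaled,
                        track.smoothed, track.gene_density,
                    ):
                        track_rows.append(
                            {
                                "cluster": f"cluster_{cid}",
                                "chrom": chrom,
                                "start": ws,
                                "end": we,
                                "raw": int(raw),
                                "scaled": round(float(scl), 6),
                                "smoothed": round(float(smo), 6),
                                "gene_density": round(float(gd), 6),
                            }
                        )
            pd.DataFrame(corr_rows).to_csv(outdir / "correlations.tsv", sep="\t", index=False)
            pd.DataFrame(track_rows).to_csv(outdir / "tracks.tsv", sep="\t", index=False)
            record("paint", outdir / "correlations.tsv", outdir / "tracks.tsv")
        except (ValueError, KeyError) as exc:
            raise StageError("paint", str(exc)) from exc

    if "structure" in stages:
        try:
            if abundance is None:
                abundance = io.read_tsv_matrix(
                    _require(outdir / "abundance.tsv", "structure")
                )
            geno = io.read_tsv_matrix(_require(outdir / "genotypes.tsv", "structure"))
            if pops is None:
                lab_df = pd.read_csv(
                    _require(outdir / "labels.tsv", "structure"), sep="\t", index_col=0
                )
                pops = lab_df["population"]
            geno = geno.loc[abundance.index]
            contrast = structure_contrast(abundance, geno, pops)
            contrast.repeat_pca.scores.to_csv(
                outdir / "repeat_pca_scores.tsv", sep="\t", index_label="id"
            )
            contrast.snp_pca.scores.to_csv(
                outdir / "snp_pca_scores.tsv", sep="\t", index_label="id"
            )
            io.write_manifest(
                {
                    "repeat_silhouette": contrast.repeat_silhouette,
                    "snp_silhouette": contrast.snp_silhouette,
                    "repeat_explained_variance": list(
                        map(float, contrast.repeat_pca.explained_variance_ratio)
                    ),
                    "snp_explained_variance": list(
                        map(float, contrast.snp_pca.explained_variance_ratio)
                    ),
                },
                outdir / "silhouettes.json",
            )
            if config.get("plots", False):
                _plot_structure(contrast, outdir)
            record(
                "structure",
                outdir / "repeat_pca_scores.tsv",
                outdir / "snp_pca_scores.tsv",
                outdir / "silhouettes.json",
            )
        except (ValueError, KeyError) as exc:
            raise StageError("structure", str(exc)) from exc

    io.write_manifest(manifest, outdir / "manifest.json")
    return outdir


def _plot_structure(contrast, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for ax, result, title in (
        (axes[0], contrast.repeat_pca, "repeat abundance PCA"),
        (axes[1], contrast.snp_pca, "SNP genotype PCA"),
    ):
        for pop, color in zip(sorted(contrast.labels.unique()), ("tab:blue", "tab:red")):
            sel = contrast.labels == pop
            ax.scatter(
                result.scores.loc[sel.values, "PC1"],
                result.scores.loc[sel.values, "PC2"],
                s=14, c=color, label=pop,
            )
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title(title)
        ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "structure_pca.png", dpi=120)
    plt.close(fig)
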