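"""File-format readers and writers for the pipeline.

All internal coordinates are 0-based half-open; conversions (GFF3's
1-based closed intervals, BED passthrough) happen only here. Read FASTA
headers use the microformat ``<individual>|<population>|<read_id>``;
library FASTA headers carry ``family=`` and ``class=`` tags.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import ClusterAnnotation
from .similarity import SimilarityHit, import_hits
from .simulate import LibraryRecord, Placement, Read, ReadSet, SyntheticGenome


# --- FASTA -----------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (header, sequence) pairs (header = full description)."""
    return [
        (rec.description or rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_reads_fasta(reads: ReadSet, path: str | Path) -> None:
    write_fasta(
        ((f"{r.individual}|{r.population}|{r.id}", r.sequence) for r in reads), path
    )


def read_reads_fasta(path: str | Path) -> ReadSet:
    """Parse reads written by write_reads_fasta (or FASTQ with the same headers)."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"{path}: header {rec.id!r} is not <individual>|<population>|<read_id>"
            )
        ind, pop, rid = parts
        out.append(Read(id=rid, sequence=str(rec.seq), individual=ind, population=pop))
    return ReadSet(out)


def write_library_fasta(library: Sequence[LibraryRecord], path: str | Path) -> None:
    write_fasta(
        (
            (f"{rec.name} family={rec.name} class={rec.class_label}", rec.sequence)
            for rec in library
        ),
        path,
    )


def read_library_fasta(path: str | Path) -> list[LibraryRecord]:
    out = []
    for header, seq in read_fasta(path):
        fields = dict(
            tok.split("=", 1) for tok in header.split()[1:] if "=" in tok
        )
        name = fields.get("family", header.split()[0])
        out.append(
            LibraryRecord(
                name=name, class_label=fields.get("class", "other"), sequence=seq
            )
        )
    return out


def write_genome_fasta(genome: SyntheticGenome, path: str | Path) -> None:
    write_fasta(genome.chromosomes.items(), path)


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {header.split()[0]: seq for header, seq in read_fasta(path)}


# --- BED / GFF3 ------------------------------------------------------------

def write_bed(
    intervals: Iterable[tuple], path: str | Path
) -> None:
    """Write BED6 rows; items are (chrom, start, end[, name[, score[, strand]]])."""
    with open(path, "w") as fh:
        for item in intervals:
            chrom, start, end = item[0], item[1], item[2]
            name = item[3] if len(item) > 3 else "."
            score = item[4] if len(item) > 4 else 0
            strand = item[5] if len(item) > 5 else "+"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read BED as (chrom, start, end, name, strand), 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: start must be < end and >= 0")
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "+"
            out.append((fields[0], start, end, name, strand))
    return out


def read_gff3(
    path: str | Path, feature_types: set[str] | None = None
) -> list[tuple[str, int, int, str, str]]:
    """Read GFF3 features as 0-based half-open (chrom, start, end, type, strand).

    GFF3 is 1-based closed: a feature at 1..100 becomes [0, 100).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: GFF3 needs >= 8 fields")
            ftype = fields[2]
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ValueError(f"{path}:{lineno}: invalid GFF3 interval")
            out.append((fields[0], start1 - 1, end1, ftype, fields[6]))
    return out


def write_truth_bed(genome: SyntheticGenome, path: str | Path) -> None:
    write_bed(
        ((p.chrom, p.start, p.end, p.family, 0, p.strand) for p in genome.truth_placements),
        path,
    )


def read_truth_bed(path: str | Path) -> list[Placement]:
    return [
        Placement(family=name, chrom=chrom, start=s, end=e, strand=strand)
        for chrom, s, e, name, strand in read_bed(path)
    ]


# --- TSV matrices and hits -------------------------------------------------

def write_tsv_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="id")


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_hits_tsv(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in BLAST outfmt-6 layout (placeholder alignment columns)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.read_a}\t{h.read_b}\t0\t0\t0\t0\t0\t0\t0\t0\t0\t{h.bitscore:g}\n"
            )


def read_hits_tsv(path: str | Path) -> list[SimilarityHit]:
    with open(path) as fh:
        return import_hits(fh)


def write_annotation_tsv(
    annotations: Sequence[ClusterAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tbest_label\tclass_label\tn_hit_reads\tn_reads\ttie\n")
        for a in annotations:
            fh.write(
                f"cluster_{a.cluster_id}\t{a.best_label}\t{a.class_label}\t"
                f"{a.n_hit_reads}\t{a.n_reads}\t{str(a.tie).lower()}\n"
            )


# --- VCF (minimal) ---------------------------------------------------------

def read_vcf_minimal(path: str | Path) -> pd.DataFrame:
    """Biallelic SNP calls from a plain-text VCF, as allele-pair strings.

    Only the GT subfield is used; missing genotypes become 'NN'. Rows are
    individuals, columns are ``chrom:pos`` marker ids.
    """
    samples: list[str] = []
    markers: list[str] = []
    columns: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(f"{path}:{lineno}: VCF has no sample columns")
                samples = fields[9:]
                continue
            if not samples:
                raise ValueError(f"{path}:{lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: truncated VCF record")
            chrom, pos, _, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if len(ref) != 1 or len(alt) != 1 or alt == "." or "," in alt:
                continue  # not a biallelic SNP
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: record lacks GT") from exc
            alleles = (ref, alt)
            calls = []
            for sample_field in fields[9:]:
                gt = sample_field.split(":")[gt_idx].replace("|", "/")
                parts = gt.split("/")
                if len(parts) != 2 or "." in parts:
                    calls.append("NN")
                    continue
                try:
                    pair = "".join(sorted(alleles[int(x)] for x in parts))
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: bad GT {gt!r}") from exc
                calls.append(pair)
            markers.append(f"{chrom}:{pos}")
            columns.append(calls)
    if not markers:
        raise ValueError(f"{path}: no biallelic SNP records found")
    data = {m: col for m, col in zip(markers, columns)}
    return pd.DataFrame(data, index=samples)


# --- manifest --------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
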