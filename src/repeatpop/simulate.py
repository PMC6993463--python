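"""Synthetic repeat libraries, genomes, populations and skim-sequencing reads.

Every generator is a pure function of its inputs and a seed, so each
downstream stage of the pipeline can be tested against known ground truth.
The mutation model is substitution-only (no indels): copy lengths and k-mer
arithmetic stay exact. All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import decode_seq, encode_seq, random_sequence, revcomp, rng_for

FAMILY_CLASSES = ("Gypsy-like", "Copia-like", "tandem", "other")


@dataclass(frozen=True)
class RepeatFamilySpec:
    """Parameters of one synthetic repeat family.

    placement_bias is in [-1, 1]: -1 seeks gene-poor regions, +1 seeks
    gene-rich regions, 0 places uniformly.
    """

    name: str
    class_label: str
    monomer_length: int
    target_copy_number: int
    intra_family_divergence: float = 0.0
    placement_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in FAMILY_CLASSES:
            raise ValueError(
                f"class_label {self.class_label!r} not in {FAMILY_CLASSES}"
            )
        if self.monomer_length < 50:
            raise ValueError("monomer_length must be >= 50")
        if self.target_copy_number < 1:
            raise ValueError("target_copy_number must be >= 1")
        if not 0.0 <= self.intra_family_divergence <= 0.3:
            raise ValueError("intra_family_divergence must be in [0, 0.3]")
        if not -1.0 <= self.placement_bias <= 1.0:
            raise ValueError("placement_bias must be in [-1, 1]")


@dataclass(frozen=True)
class LibraryRecord:
    """One ancestral monomer with its family metadata."""

    name: str
    class_label: str
    sequence: str
    spec: RepeatFamilySpec | None = None


@dataclass(frozen=True)
class Placement:
    """One planted repeat copy (0-based, half-open)."""

    family: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    genes: list[tuple[str, int, int]]
    truth_placements: list[Placement]

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def repeat_fraction(self) -> float:
        """Planted repeat bp / total genome bp."""
        total = sum(len(s) for s in self.chromosomes.values())
        planted = sum(p.end - p.start for p in self.truth_placements)
        return planted / total if total else 0.0


@dataclass(frozen=True)
class Read:
    """A single shotgun read carrying individual/population identity.

    chrom/start/strand record the true sampling location (provenance for
    truth-based tests); fragment groups paired reads.
    """

    id: str
    sequence: str
    individual: str
    population: str
    fragment: str | None = None
    chrom: str | None = None
    start: int | None = None
    strand: str | None = None


class ReadSet:
    """An ordered collection of labelled reads."""

    def __init__(self, reads: Iterable[Read] = ()):
        self.reads: list[Read] = list(reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i: int) -> Read:
        return self.reads[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.reads]

    def labels(self) -> dict[str, tuple[str, str]]:
        """read id -> (individual, population)."""
        return {r.id: (r.individual, r.population) for r in self.reads}

    def extend(self, other: "ReadSet") -> None:
        self.reads.extend(other.reads)


@dataclass(frozen=True)
class PopulationConfig:
    """Two-population study design used by :func:`simulate_population`."""

    n_individuals_per_pop: int
    pop_labels: tuple[str, str] = ("SS", "NSS")
    snp_count: int = 100
    snp_divergence: float = 0.0
    repeat_effect: Mapping[str, float] | float = 1.0
    heterozygosity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals_per_pop < 2:
            raise ValueError("n_individuals_per_pop must be >= 2")
        if self.snp_count < 2:
            raise ValueError("snp_count must be >= 2")
        if not 0.0 <= self.snp_divergence <= 0.5:
            raise ValueError("snp_divergence must be in [0, 0.5]")
        if not 0.0 <= self.heterozygosity_rate <= 1.0:
            raise ValueError("heterozygosity_rate must be in [0, 1]")
        if len(self.pop_labels) != 2 or self.pop_labels[0] == self.pop_labels[1]:
            raise ValueError("pop_labels must be two distinct labels")


def make_repeat_library(
    specs: Sequence[RepeatFamilySpec], seed: int
) -> list[LibraryRecord]:
    """One uniform-random ancestral monomer per family spec.

    Deterministic per seed; duplicate family names are rejected.
    """
    if not specs:
        raise ValueError("at least one family spec is required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate family names in library: {dup}")
    records = []
    for spec in specs:
        rng = rng_for(seed, f"library/{spec.name}")
        records.append(
            LibraryRecord(
                name=spec.name,
                class_label=spec.class_label,
                sequence=random_sequence(rng, spec.monomer_length),
                spec=spec,
            )
        )
    return records


def evolve_family_copies(
    monomer: str, n_copies: int, divergence: float, seed: int
) -> list[str]:
    """Independently mutated copies of a monomer (substitution-only).

    Each site mutates with probability ``divergence`` to one of the three
    other bases, chosen uniformly.
    """
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    if n_copies == 0:
        return []
    rng = rng_for(seed, "evolve")
    codes = encode_seq(monomer)
    if (codes > 3).any():
        raise ValueError("monomer must be over ACGT")
    n = len(codes)
    mask = rng.random((n_copies, n)) < divergence
    # offset 1..3 guarantees a substitution changes the base
    offsets = rng.integers(1, 4, size=(n_copies, n), dtype=np.uint8)
    mutated = (codes[None, :] + offsets * mask) % 4
    return [decode_seq(row) for row in mutated.astype(np.uint8)]


def linear_gene_gradient(x: np.ndarray) -> np.ndarray:
    """Default gene-density profile: linearly decreasing along the chromosome."""
    return 2.0 * (1.0 - x) + 0.05


def _place_genes(
    rng: np.random.Generator,
    chrom_len: int,
    n_genes: int,
    gene_length: int,
    profile: Callable[[np.ndarray], np.ndarray],
) -> list[tuple[int, int]]:
    """Sample non-overlapping gene intervals along a density gradient."""
    if chrom_len <= gene_length or n_genes == 0:
        return []
    n_bins = min(512, max(8, chrom_len // (2 * gene_length)))
    mids = (np.arange(n_bins) + 0.5) / n_bins
    weights = np.asarray(profile(mids), dtype=float)
    weights = np.clip(weights, 0.0, None)
    if weights.sum() <= 0:
        weights = np.ones(n_bins)
    weights = weights / weights.sum()
    max_start = chrom_len - gene_length
    chosen: list[tuple[int, int]] = []
    # draw a surplus of candidates, keep the non-overlapping ones
    bins = rng.choice(n_bins, size=6 * n_genes, p=weights)
    offsets = rng.random(6 * n_genes)
    for b, off in zip(bins, offsets):
        lo = int(b / n_bins * max_start)
        hi = int((b + 1) / n_bins * max_start)
        start = min(max_start, lo + int(off * max(1, hi - lo)))
        end = start + gene_length
        if any(start < e and end > s for s, e in chosen):
            continue
        chosen.append((start, end))
        if len(chosen) >= n_genes:
            break
    chosen.sort()
    return chosen


def _bias_weights(
    gene_cov: np.ndarray, bias: float
) -> np.ndarray:
    """Per-bin sampling weights mixing uniform with (anti-)gene-density.

    The density signal is sharpened with an exponent growing in |bias| so
    that |bias| = 1 concentrates insertions strongly at the corresponding
    extreme of the gene-density gradient.
    """
    n = len(gene_cov)
    uniform = np.full(n, 1.0 / n)
    if bias == 0.0:
        return uniform
    if bias > 0:
        signal = gene_cov + 1e-9
    else:
        signal = (gene_cov.max() - gene_cov) + 1e-9
    signal = (signal / signal.max()) ** (1.0 + 3.0 * abs(bias))
    signal = signal / signal.sum()
    w = (1.0 - abs(bias)) * uniform + abs(bias) * signal
    return w / w.sum()


def build_genome(
    library: Sequence[LibraryRecord],
    copy_plan: Mapping[str, int] | None,
    chrom_lengths: Mapping[str, int],
    seed: int,
    n_genes_per_chrom: int = 40,
    gene_length: int = 2000,
    gene_density_profile: Callable[[np.ndarray], np.ndarray] = linear_gene_gradient,
    bias_bin_size: int = 10_000,
) -> SyntheticGenome:
    """Assemble chromosomes of random background, genes, and planted repeats.

    Genes are placed first along the density profile; repeat copies are then
    written over the background at positions drawn according to each family's
    placement_bias relative to realized gene density. tandem-class families
    are laid head-to-tail at a single locus. Every insertion is recorded in
    truth_placements.
    """
    by_name = {rec.name: rec for rec in library}
    plan: dict[str, int] = {}
    for rec in library:
        n = (
            copy_plan.get(rec.name, 0)
            if copy_plan is not None
            else (rec.spec.target_copy_number if rec.spec else 0)
        )
        if n:
            plan[rec.name] = int(n)
    if copy_plan:
        unknown = set(copy_plan) - set(by_name)
        if unknown:
            raise ValueError(f"copy plan names not in library: {sorted(unknown)}")

    total_len = sum(chrom_lengths.values())
    cumulative = 0
    for name, n in plan.items():
        cumulative += n * len(by_name[name].sequence)
        if cumulative >= total_len:
            raise ValueError(
                f"genome over-filled: family {name!r} does not fit "
                f"({cumulative} planted bp >= {total_len} bp genome)"
            )

    rng = rng_for(seed, "genome")
    chrom_names = list(chrom_lengths)
    chroms: dict[str, np.ndarray] = {}
    genes: list[tuple[str, int, int]] = []
    gene_cov: dict[str, np.ndarray] = {}
    bias_w: dict[str, dict[float, np.ndarray]] = {}

    for cname in chrom_names:
        clen = int(chrom_lengths[cname])
        chroms[cname] = encode_seq(random_sequence(rng, clen))
        for s, e in _place_genes(
            rng, clen, n_genes_per_chrom, gene_length, gene_density_profile
        ):
            genes.append((cname, s, e))
        nbins = max(1, math.ceil(clen / bias_bin_size))
        cov = np.zeros(nbins)
        for gchrom, s, e in genes:
            if gchrom != cname:
                continue
            b0, b1 = s // bias_bin_size, (e - 1) // bias_bin_size
            for b in range(b0, b1 + 1):
                lo = max(s, b * bias_bin_size)
                hi = min(e, min((b + 1) * bias_bin_size, clen))
                cov[b] += hi - lo
        bin_sizes = np.minimum(
            bias_bin_size, clen - np.arange(nbins) * bias_bin_size
        )
        gene_cov[cname] = cov / bin_sizes
        bias_w[cname] = {}

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    placements: list[Placement] = []
    lens = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_p = lens / lens.sum()

    def sample_start(cname: str, bias: float, span: int) -> int | None:
        clen = chrom_lengths[cname]
        if span > clen:
            return None
        w = bias_w[cname].get(bias)
        if w is None:
            w = _bias_weights(gene_cov[cname], bias)
            bias_w[cname][bias] = w
        for _ in range(200):
            b = rng.choice(len(w), p=w)
            lo = b * bias_bin_size
            hi = min((b + 1) * bias_bin_size, clen)
            start = int(rng.integers(lo, hi))
            if start + span > clen:
                continue
            end = start + span
            if any(start < e and end > s for s, e in occupied[cname]):
                continue
            return start
        # rejection failed (large span or crowded chromosome): scan free gaps
        taken = sorted(occupied[cname])
        gaps: list[tuple[int, int]] = []
        cursor = 0
        for s, e in taken:
            if s - cursor >= span:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if clen - cursor >= span:
            gaps.append((cursor, clen))
        if not gaps:
            return None
        cand = [s for s, e in gaps]
        cand_w = np.array([w[min(s // bias_bin_size, len(w) - 1)] + 1e-12 for s in cand])
        pick = int(rng.choice(len(cand), p=cand_w / cand_w.sum()))
        gs, ge = gaps[pick]
        return int(rng.integers(gs, ge - span + 1))

    # tandem families first: they need contiguous space that dispersed
    # copies would otherwise fragment
    def _is_tandem(fam: str) -> bool:
        s = by_name[fam].spec
        return s is not None and s.class_label == "tandem"

    ordered = sorted(plan, key=lambda fam: (not _is_tandem(fam), fam))
    for fam in ordered:
        n_copies = plan[fam]
        rec = by_name[fam]
        spec = rec.spec
        divergence = spec.intra_family_divergence if spec else 0.0
        bias = spec.placement_bias if spec else 0.0
        is_tandem = spec is not None and spec.class_label == "tandem"
        copies = evolve_family_copies(
            rec.sequence, n_copies, divergence, int(rng.integers(2**31))
        )
        if is_tandem:
            mono = len(rec.sequence)
            span = mono * n_copies
            cname = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
            start = sample_start(cname, bias, span)
            if start is None:
                raise ValueError(
                    f"genome over-filled: no room for tandem family {fam!r}"
                )
            occupied[cname].append((start, start + span))
            arr = chroms[cname]
            for i, copy in enumerate(copies):
                s = start + i * mono
                arr[s : s + mono] = encode_seq(copy)
                placements.append(Placement(fam, cname, s, s + mono, "+"))
        else:
            for copy in copies:
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = copy if strand == "+" else revcomp(copy)
                cname = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
                start = sample_start(cname, bias, len(inserted))
                if start is None:
                    raise ValueError(
                        f"genome over-filled: no room for family {fam!r}"
                    )
                end = start + len(inserted)
                occupied[cname].append((start, end))
                chroms[cname][start:end] = encode_seq(inserted)
                placements.append(Placement(fam, cname, start, end, strand))

    return SyntheticGenome(
        chromosomes={c: decode_seq(a) for c, a in chroms.items()},
        genes=sorted(genes),
        truth_placements=placements,
    )


def simulate_population(
    genome: SyntheticGenome, config: PopulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-individual repeat copy numbers and SNP genotype calls.

    SNP allele frequencies for the two populations are drawn from a
    symmetric Balding-Nichols model: the ancestral major-allele frequency
    p ~ Uniform(0.1, 0.9) per marker, and each population's frequency is an
    independent Beta(p(1-F)/F, (1-p)(1-F)/F) draw with F = snp_divergence
    (F = 0 degenerates to both populations at p). Individuals are inbred:
    calls are homozygous draws at the population frequency, with
    heterozygous calls injected at heterozygosity_rate. Per-family copy
    numbers are Poisson around the population mean; the second population's
    mean is the first's times repeat_effect[family].

    Returns (copy-number table, genotype call table, population labels).
    """
    rng = rng_for(config.seed, "population")
    families = sorted({p.family for p in genome.truth_placements})
    base_counts = {
        fam: sum(1 for p in genome.truth_placements if p.family == fam)
        for fam in families
    }
    if isinstance(config.repeat_effect, Mapping):
        effects = {fam: float(config.repeat_effect.get(fam, 1.0)) for fam in families}
    else:
        effects = {fam: float(config.repeat_effect) for fam in families}
    bad = [f for f, v in effects.items() if v <= 0]
    if bad:
        raise ValueError(f"repeat_effect must be > 0 (violated for {bad})")

    n = config.n_individuals_per_pop
    pop1, pop2 = config.pop_labels
    individuals = [f"{pop1}_{i:03d}" for i in range(n)] + [
        f"{pop2}_{i:03d}" for i in range(n)
    ]
    labels = pd.Series([pop1] * n + [pop2] * n, index=individuals, name="population")

    copy_rows = np.zeros((2 * n, len(families)), dtype=int)
    for j, fam in enumerate(families):
        mean1 = max(base_counts[fam], 1)
        mean2 = mean1 * effects[fam]
        copy_rows[:n, j] = rng.poisson(mean1, size=n)
        copy_rows[n:, j] = rng.poisson(mean2, size=n)
    copy_df = pd.DataFrame(copy_rows, index=individuals, columns=families)

    m = config.snp_count
    p_anc = rng.uniform(0.1, 0.9, size=m)
    F = config.snp_divergence
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    else:
        p1 = p_anc.copy()
        p2 = p_anc.copy()

    base_pairs = np.array(["AC", "AG", "AT", "CG", "CT", "GT"])
    pairs = rng.choice(base_pairs, size=m)
    geno = np.empty((2 * n, m), dtype=object)
    for j in range(m):
        ref, alt = pairs[j][0], pairs[j][1]
        freqs = np.concatenate([np.full(n, p1[j]), np.full(n, p2[j])])
        is_ref = rng.random(2 * n) < freqs
        calls = np.where(is_ref, ref + ref, alt + alt)
        if config.heterozygosity_rate > 0:
            het = rng.random(2 * n) < config.heterozygosity_rate
            calls = np.where(het, ref + alt, calls)
        geno[:, j] = calls
    geno_df = pd.DataFrame(
        geno, index=individuals, columns=[f"snp_{j:04d}" for j in range(m)]
    )
    return copy_df, geno_df, labels


def shotgun_reads(
    genome: SyntheticGenome,
    n_reads: int,
    read_length: int,
    seed: int,
    individual: str = "ind0",
    population: str = "pop1",
    paired: bool = False,
    insert_gap: int = 50,
) -> ReadSet:
    """Uniform shotgun reads from a genome, strand chosen uniformly.

    With paired=True, fragments of 2*read_length + insert_gap yield two
    reads sharing a fragment id (second read is the reverse complement of
    the fragment end).
    """
    if n_reads == 0:
        return ReadSet()
    rng = rng_for(seed, f"shotgun/{individual}")
    chrom_names = list(genome.chromosomes)
    min_len = min(len(s) for s in genome.chromosomes.values())
    span = (2 * read_length + insert_gap) if paired else read_length
    if span > min_len:
        raise ValueError(
            f"sampled span {span} exceeds shortest chromosome ({min_len} bp)"
        )
    weights = np.array(
        [len(genome.chromosomes[c]) - span + 1 for c in chrom_names], dtype=float
    )
    weights = weights / weights.sum()
    n_frags = n_reads
    cidx = rng.choice(len(chrom_names), size=n_frags, p=weights)
    strands = rng.random(n_frags) < 0.5
    reads: list[Read] = []
    for i in range(n_frags):
        cname = chrom_names[cidx[i]]
        seq = genome.chromosomes[cname]
        start = int(rng.integers(0, len(seq) - span + 1))
        if paired:
            frag_id = f"{individual}_f{i}"
            s1 = seq[start : start + read_length]
            s2 = revcomp(seq[start + span - read_length : start + span])
            reads.append(
                Read(
                    f"{individual}_r{i}a", s1, individual, population,
                    fragment=frag_id, chrom=cname, start=start, strand="+",
                )
            )
            reads.append(
                Read(
                    f"{individual}_r{i}b", s2, individual, population,
                    fragment=frag_id, chrom=cname,
                    start=start + span - read_length, strand="-",
                )
            )
        else:
            s = seq[start : start + read_length]
            strand = "+"
            if strands[i]:
                s = revcomp(s)
                strand = "-"
            reads.append(
                Read(
                    f"{individual}_r{i}", s, individual, population,
                    chrom=cname, start=start, strand=strand,
                )
            )
    return ReadSet(reads)


def downsample_reads(reads: ReadSet, n: int, seed: int) -> ReadSet:
    """Sample n reads without replacement, at most one read per fragment."""
    rng = rng_for(seed, "downsample")
    by_fragment: dict[str, list[int]] = {}
    for i, r in enumerate(reads):
        key = r.fragment if r.fragment is not None else f"__solo_{i}"
        by_fragment.setdefault(key, []).append(i)
    pool = [
        members[int(rng.integers(len(members)))] if len(members) > 1 else members[0]
        for members in by_fragment.values()
    ]
    if n > len(pool):
        raise ValueError(
            f"cannot downsample to {n}: only {len(pool)} fragment-distinct reads"
        )
    if n == 0:
        return ReadSet()
    chosen = rng.choice(len(pool), size=n, replace=False)
    keep = sorted(pool[i] for i in chosen)
    return ReadSet(reads[i] for i in keep)


def assign_read_origins(
    reads: ReadSet, genome: SyntheticGenome, min_overlap: float = 0.5
) -> dict[str, str]:
    """Map each read to the planted family it was sampled from.

    A read belongs to a family if >= min_overlap of its span overlaps one of
    that family's truth placements; otherwise it is 'background'. Requires
    reads with provenance coordinates (as produced by shotgun_reads).
    """
    by_chrom: dict[str, list[Placement]] = {}
    for p in genome.truth_placements:
        by_chrom.setdefault(p.chrom, []).append(p)
    starts: dict[str, np.ndarray] = {}
    for c, plist in by_chrom.items():
        plist.sort(key=lambda p: p.start)
        starts[c] = np.array([p.start for p in plist])
    origins: dict[str, str] = {}
    for r in reads:
        if r.chrom is None or r.start is None:
            raise ValueError(f"read {r.id} has no provenance coordinates")
        origins[r.id] = "background"
        plist = by_chrom.get(r.chrom)
        if not plist:
            continue
        r_end = r.start + len(r.sequence)
        i = int(np.searchsorted(starts[r.chrom], r_end))
        best_fam, best_ov = None, 0
        for p in plist[max(0, i - 50) : i]:
            ov = min(p.end, r_end) - max(p.start, r.start)
            if ov > best_ov:
                best_ov, best_fam = ov, p.family
        if best_fam is not None and best_ov >= min_overlap * len(r.sequence):
            origins[r.id] = best_fam
    return origins


def gene_density_at(genome: SyntheticGenome, chrom: str, start: int, end: int,
                    flank: int = 10_000) -> float:
    """Fraction of [start-flank, end+flank) covered by gene intervals."""
    lo = max(0, start - flank)
    hi = min(len(genome.chromosomes[chrom]), end + flank)
    cov = 0
    for gchrom, gs, ge in genome.genes:
        if gchrom != chrom:
            continue
        cov += max(0, min(ge, hi) - max(gs, lo))
    return cov / (hi - lo) if hi > lo else 0.0
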