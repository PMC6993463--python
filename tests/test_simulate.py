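import numpy as np
import pytest

from repeatpop import simulate as sim


def specs_of(**kwargs):
    defaults = dict(
        name="fam",
        class_label="other",
        monomer_length=500,
        target_copy_number=10,
        intra_family_divergence=0.0,
        placement_bias=0.0,
    )
    defaults.update(kwargs)
    return sim.RepeatFamilySpec(**defaults)


class TestFamilySpec:
    def test_rejects_bad_class(self):
        with pytest.raises(ValueError):
            specs_of(class_label="LINE")

    def test_rejects_short_monomer(self):
        with pytest.raises(ValueError):
            specs_of(monomer_length=49)

    @pytest.mark.parametrize("divergence", [-0.1, 0.31])
    def test_rejects_divergence_out_of_range(self, divergence):
        with pytest.raises(ValueError):
            specs_of(intra_family_divergence=divergence)


class TestMakeRepeatLibrary:
    def test_length_forced_by_spec(self):
        lib = sim.make_repeat_library([specs_of(monomer_length=500)], seed=7)
        assert len(lib) == 1
        assert len(lib[0].sequence) == 500

    def test_deterministic_per_seed(self):
        a = sim.make_repeat_library([specs_of()], seed=7)
        b = sim.make_repeat_library([specs_of()], seed=7)
        assert a[0].sequence == b[0].sequence
        c = sim.make_repeat_library([specs_of()], seed=8)
        assert c[0].sequence != a[0].sequence

    def test_three_specs_three_records(self):
        specs = [specs_of(name=n, class_label=c) for n, c in
                 [("a", "Gypsy-like"), ("b", "Copia-like"), ("c", "tandem")]]
        lib = sim.make_repeat_library(specs, seed=0)
        assert [r.name for r in lib] == ["a", "b", "c"]
        assert [r.class_label for r in lib] == ["Gypsy-like", "Copia-like", "tandem"]

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sim.make_repeat_library([specs_of(name="x"), specs_of(name="x")], seed=0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sim.make_repeat_library([], seed=0)


class TestEvolveFamilyCopies:
    def test_zero_divergence_identical(self):
        monomer = "ACGT" * 50
        copies = sim.evolve_family_copies(monomer, 5, 0.0, seed=1)
        assert copies == [monomer] * 5

    def test_mean_identity_matches_binomial_expectation(self):
        # oracle: direct mismatch count; per-site retention 0.9
        monomer = sim.make_repeat_library([specs_of(monomer_length=500)], 3)[0].sequence
        n_copies, divergence = 200, 0.1
        copies = sim.evolve_family_copies(monomer, n_copies, divergence, seed=1)
        identities = [
            sum(a == b for a, b in zip(monomer, c)) / len(monomer) for c in copies
        ]
        se = np.sqrt(divergence * (1 - divergence) / len(monomer) / n_copies)
        assert abs(np.mean(identities) - 0.9) < 3 * se

    def test_substitution_only_preserves_length(self):
        monomer = sim.make_repeat_library([specs_of(monomer_length=500)], 5)[0].sequence
        for c in sim.evolve_family_copies(monomer, 20, 0.05, seed=2):
            assert len(c) == 500

    def test_zero_copies_empty(self):
        assert sim.evolve_family_copies("A" * 100, 0, 0.1, seed=0) == []

    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError):
            sim.evolve_family_copies("A" * 100, 2, 0.5, seed=0)

    def test_deterministic(self):
        a = sim.evolve_family_copies("ACGT" * 30, 10, 0.2, seed=9)
        b = sim.evolve_family_copies("ACGT" * 30, 10, 0.2, seed=9)
        assert a == b


class TestBuildGenome:
    def test_bias_sign_recovered_from_truth(self):
        specs = [
            specs_of(name="poor", target_copy_number=60, placement_bias=-1.0),
            specs_of(name="rich", target_copy_number=60, placement_bias=1.0),
        ]
        lib = sim.make_repeat_library(specs, 4)
        genome = sim.build_genome(lib, None, {"chr1": 500_000}, 4, n_genes_per_chrom=60)
        means = {}
        for fam in ("poor", "rich"):
            ds = [
                sim.gene_density_at(genome, p.chrom, p.start, p.end)
                for p in genome.truth_placements
                if p.family == fam
            ]
            means[fam] = np.mean(ds)
        assert means["poor"] < means["rich"]

    def test_tandem_contiguous_block(self):
        specs = [specs_of(name="tan", class_label="tandem", monomer_length=180,
                          target_copy_number=300, intra_family_divergence=0.01)]
        lib = sim.make_repeat_library(specs, 5)
        genome = sim.build_genome(lib, None, {"chr1": 200_000}, 5)
        placements = sorted(
            (p for p in genome.truth_placements if p.family == "tan"),
            key=lambda p: p.start,
        )
        assert len(placements) == 300
        # head-to-tail: each copy starts where the previous one ends
        for prev, cur in zip(placements, placements[1:]):
            assert cur.start == prev.end
        total = placements[-1].end - placements[0].start
        assert total == 300 * 180  # ~54 kb single locus

    def test_empty_copy_plan(self):
        lib = sim.make_repeat_library([specs_of()], 0)
        genome = sim.build_genome(lib, {}, {"chr1": 50_000}, 0)
        assert genome.truth_placements == []
        assert genome.genes
        assert len(genome.chromosomes["chr1"]) == 50_000

    def test_overfilled_names_family(self):
        specs = [specs_of(name="huge", monomer_length=1000, target_copy_number=200)]
        lib = sim.make_repeat_library(specs, 0)
        with pytest.raises(ValueError, match="huge"):
            sim.build_genome(lib, None, {"chr1": 100_000}, 0)

    def test_intervals_within_bounds(self, small_genome):
        _, genome = small_genome
        lengths = genome.chrom_lengths()
        for chrom, s, e in genome.genes:
            assert 0 <= s < e <= lengths[chrom]
        for p in genome.truth_placements:
            assert 0 <= p.start < p.end <= lengths[p.chrom]

    def test_truth_conservation(self, three_family_specs, small_genome):
        # planted fraction equals the plan within rounding
        _, genome = small_genome
        planned = sum(
            s.monomer_length * s.target_copy_number for s in three_family_specs
        )
        planted = sum(p.end - p.start for p in genome.truth_placements)
        assert planted == planned

    def test_placed_sequence_matches_truth_strand(self):
        spec = specs_of(name="f", target_copy_number=5, intra_family_divergence=0.0)
        lib = sim.make_repeat_library([spec], 11)
        genome = sim.build_genome(lib, None, {"chr1": 60_000}, 11)
        from repeatpop._utils import revcomp

        for p in genome.truth_placements:
            segment = genome.chromosomes[p.chrom][p.start:p.end]
            expected = lib[0].sequence if p.strand == "+" else revcomp(lib[0].sequence)
            assert segment == expected

    def test_deterministic(self, three_family_specs):
        lib = sim.make_repeat_library(three_family_specs, 1)
        g1 = sim.build_genome(lib, None, {"chr1": 100_000}, 1)
        g2 = sim.build_genome(lib, None, {"chr1": 100_000}, 1)
        assert g1.chromosomes == g2.chromosomes
        assert g1.truth_placements == g2.truth_placements


class TestSimulatePopulation:
    def test_null_snp_divergence_centered(self, small_genome):
        # oracle: direct major-allele frequency computation per population
        _, genome = small_genome
        cfg = sim.PopulationConfig(
            n_individuals_per_pop=50, snp_count=1000, snp_divergence=0.0, seed=3
        )
        _, geno, labels = sim.simulate_population(genome, cfg)
        diffs = []
        for marker in geno.columns:
            col = geno[marker]
            freqs = {}
            for pop in cfg.pop_labels:
                calls = col[labels == pop]
                alleles = "".join(calls)
                counts = {a: alleles.count(a) for a in set(alleles)}
                major = max(sorted(counts), key=lambda a: counts[a])
                freqs[pop] = counts[major] / len(alleles)
            diffs.append(freqs[cfg.pop_labels[0]] - freqs[cfg.pop_labels[1]])
        assert abs(np.mean(diffs)) < 0.01

    def test_repeat_effect_scales_means(self, small_genome):
        _, genome = small_genome
        cfg = sim.PopulationConfig(
            n_individuals_per_pop=40,
            snp_count=10,
            repeat_effect={"famA": 2.0},
            seed=4,
        )
        copy_df, _, labels = sim.simulate_population(genome, cfg)
        pop1, pop2 = cfg.pop_labels
        ratio = (
            copy_df.loc[labels == pop2, "famA"].mean()
            / copy_df.loc[labels == pop1, "famA"].mean()
        )
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_bad_repeat_effect_rejected(self, small_genome):
        _, genome = small_genome
        cfg = sim.PopulationConfig(
            n_individuals_per_pop=4, snp_count=5, repeat_effect=0.0, seed=0
        )
        with pytest.raises(ValueError, match="repeat_effect"):
            sim.simulate_population(genome, cfg)

    def test_heterozygosity_rate(self, small_genome):
        _, genome = small_genome
        cfg = sim.PopulationConfig(
            n_individuals_per_pop=50, snp_count=200, heterozygosity_rate=0.2, seed=5
        )
        _, geno, _ = sim.simulate_population(genome, cfg)
        het = (geno.map(lambda c: c[0] != c[1])).to_numpy().mean()
        assert het == pytest.approx(0.2, abs=0.02)

    def test_deterministic(self, small_genome):
        _, genome = small_genome
        cfg = sim.PopulationConfig(n_individuals_per_pop=5, snp_count=20, seed=6)
        a = sim.simulate_population(genome, cfg)
        b = sim.simulate_population(genome, cfg)
        assert a[0].equals(b[0]) and a[1].equals(b[1])


class TestShotgunReads:
    def test_skim_scale_counts_and_length(self, small_genome):
        _, genome = small_genome
        reads = sim.shotgun_reads(genome, 50_000, 150, 7)
        assert len(reads) == 50_000
        assert all(len(r.sequence) == 150 for r in reads.reads[:100])
        assert len({len(r.sequence) for r in reads}) == 1

    def test_repeat_read_fraction_tracks_genome_fraction(self, small_genome):
        _, genome = small_genome
        frac = genome.repeat_fraction()
        reads = sim.shotgun_reads(genome, 4000, 150, 8)
        origins = sim.assign_read_origins(reads, genome, min_overlap=0.5)
        observed = np.mean([o != "background" for o in origins.values()])
        # reads must overlap a placement by >= 50%; expected within a few
        # sampling errors of the genomic repeat fraction
        assert abs(observed - frac) < 0.05

    def test_strand_reverse_complement_emitted(self, small_genome):
        from repeatpop._utils import revcomp

        _, genome = small_genome
        reads = sim.shotgun_reads(genome, 50, 100, 9)
        for r in reads:
            source = genome.chromosomes[r.chrom][r.start : r.start + 100]
            assert r.sequence == (source if r.strand == "+" else revcomp(source))

    def test_deterministic(self, small_genome):
        _, genome = small_genome
        a = sim.shotgun_reads(genome, 100, 150, 10)
        b = sim.shotgun_reads(genome, 100, 150, 10)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_zero_reads(self, small_genome):
        _, genome = small_genome
        assert len(sim.shotgun_reads(genome, 0, 150, 0)) == 0

    def test_read_longer_than_chromosome_rejected(self, small_genome):
        _, genome = small_genome
        with pytest.raises(ValueError):
            sim.shotgun_reads(genome, 10, 200_000, 0)


class TestDownsampleReads:
    def test_paired_one_read_per_fragment(self, small_genome):
        _, genome = small_genome
        reads = sim.shotgun_reads(genome, 2000, 150, 11, paired=True)
        assert len(reads) == 4000
        sampled = sim.downsample_reads(reads, 1000, 12)
        assert len(sampled) == 1000
        fragments = [r.fragment for r in sampled]
        assert len(set(fragments)) == len(fragments)

    def test_n_equals_available_identity(self, small_genome):
        _, genome = small_genome
        reads = sim.shotgun_reads(genome, 50, 150, 13)
        sampled = sim.downsample_reads(reads, 50, 14)
        assert sorted(sampled.ids()) == sorted(reads.ids())

    def test_zero(self, small_genome):
        _, genome = small_genome
        reads = sim.shotgun_reads(genome, 10, 150, 15)
        assert len(sim.downsample_reads(reads, 0, 0)) == 0

    def test_too_many_rejected(self, small_genome):
        _, genome = small_genome
        reads = sim.shotgun_reads(genome, 10, 150, 16)
        with pytest.raises(ValueError, match="downsample"):
            sim.downsample_reads(reads, 11, 0)

    def test_deterministic(self, small_genome):
        _, genome = small_genome
        reads = sim.shotgun_reads(genome, 100, 150, 17)
        a = sim.downsample_reads(reads, 30, 18)
        b = sim.downsample_reads(reads, 30, 18)
        assert a.ids() == b.ids()
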