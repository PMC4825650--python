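"""Generator invariants: determinism, valid gene models, planted truth."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

import parentdiff as pdx
from parentdiff.errors import SizingError, ValidationError
from parentdiff.genetics import STOP_CODONS


class TestTrioGeneration:
    def test_same_seed_identical_outputs(self):
        cfg = dict(seed=9, n_chromosomes=2, chromosome_length=40_000,
                   n_genes=10, mean_cds_length=150)
        a = pdx.generate_genome_trio(pdx.SimulationConfig(**cfg))
        b = pdx.generate_genome_trio(pdx.SimulationConfig(**cfg))
        assert a.reference == b.reference
        assert a.parent1_calls == b.parent1_calls
        assert a.parent2_calls == b.parent2_calls
        assert a.truth == b.truth
        assert a.go_table == b.go_table

    def test_gene_models_have_valid_reading_frames(self, trio):
        for m in trio.models:
            cds = m.cds_sequence(trio.reference)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in STOP_CODONS
            protein = str(Seq(cds).translate())
            assert "*" not in protein[:-1]  # no internal stops

    def test_callable_masks_cover_requested_fraction(self, trio):
        for chrom, ivs in trio.callable_intervals.items():
            covered = sum(e - s for s, e in ivs)
            assert covered / len(trio.reference[chrom]) == pytest.approx(
                0.82, abs=0.01)

    def test_zero_rate_parent_has_only_hemi_artifacts(self):
        cfg = pdx.SimulationConfig(seed=5, n_chromosomes=2,
                                   chromosome_length=40_000, n_genes=10,
                                   mean_cds_length=150,
                                   mutation_rate_parent1=0.0,
                                   shared_fraction=0.0)
        trio = pdx.generate_genome_trio(cfg)
        assert all(0.25 <= c.alt_frequency <= 0.75 for c in trio.parent1_calls)
        assert trio.truth.variants_of("parent1") == []

    def test_hemi_artifacts_are_the_only_non_fixed_calls(self, trio):
        hemi_truth = {(c, p) for c, p, parent, alt in trio.truth.hemi_artifacts}
        for call in trio.parent1_calls + trio.parent2_calls:
            if (call.chromosome, call.position) in hemi_truth:
                assert call.alt_frequency < 1.0
            else:
                assert call.alt_frequency == 1.0

    def test_planted_variants_inside_chromosomes(self, trio):
        for chrom, pos, parent, ref, alt, eff in trio.truth.planted_variants:
            assert 0 <= pos < len(trio.reference[chrom])
            assert trio.reference[chrom][pos] == ref
            assert eff in ("noncoding", "synonymous", "nonsynonymous")

    def test_planted_count_within_binomial_interval(self):
        """Noncoding planted SNPs at rate 0.002 fall in the central 99%
        binomial interval of the callable noncoding size."""
        cfg = pdx.SimulationConfig(seed=17, n_chromosomes=2,
                                   chromosome_length=150_000, n_genes=10,
                                   mean_cds_length=150,
                                   mutation_rate_parent1=0.002,
                                   mutation_rate_parent2=0.0,
                                   shared_fraction=0.0,
                                   hemi_snp_fraction=0.0,
                                   c_genome_rate_scale=1.0)
        trio = pdx.generate_genome_trio(cfg)
        coding = sum(3 * m.codon_count for m in trio.models)
        n_sites = sum(trio.callable_lengths.values()) - coding  # approx
        planted = sum(1 for v in trio.truth.planted_variants
                      if v[5] == "noncoding")
        lo, hi = stats.binom.ppf([0.005, 0.995], n_sites, 0.002)
        assert lo <= planted <= hi

    def test_chromosome_too_short_raises_sizing_error(self):
        cfg = pdx.SimulationConfig(seed=1, n_chromosomes=1,
                                   chromosome_length=2_000, n_genes=4,
                                   mean_cds_length=400)
        with pytest.raises(SizingError):
            pdx.generate_genome_trio(cfg)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError):
            pdx.generate_genome_trio(
                pdx.SimulationConfig(seed=1, callable_fraction=1.5))

    def test_enriched_term_genes_carry_extra_nonsynonymous_load(self, trio):
        term = trio.truth.enriched_term
        enriched = {g for g, t in trio.go_table if t == term}
        loads = {m.gene_id: 0 for m in trio.models}
        for chrom, pos, parent, ref, alt, eff in trio.truth.planted_variants:
            if eff != "nonsynonymous":
                continue
            for m in trio.models:
                if m.chromosome == chrom and m.contains(pos):
                    loads[m.gene_id] += 1
        codons = {m.gene_id: m.codon_count for m in trio.models}
        rate_in = (sum(loads[g] for g in enriched)
                   / sum(codons[g] for g in enriched))
        rest = [g for g in loads if g not in enriched]
        rate_out = (sum(loads[g] for g in rest)
                    / sum(codons[g] for g in rest))
        assert rate_in > 2 * rate_out


class TestDhPopulation:
    def test_markers_zero_cm_apart_identical(self):
        pop = pdx.generate_dh_population(400, [0.0, 15.0, 15.0, 30.0], [],
                                         0.0, seed=3)
        assert np.array_equal(pop.genotypes[:, 1], pop.genotypes[:, 2])

    def test_recombinant_fraction_matches_inverse_kosambi(self):
        d = pdx.kosambi_to_cM(0.25)  # approx 27.47 cM
        pop = pdx.generate_dh_population(10_000, [0.0, d], [], 0.0, seed=4)
        rf = float(np.mean(pop.genotypes[:, 0] != pop.genotypes[:, 1]))
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(rf - 0.25) < 4 * se

    def test_heritability_zero_phenotype_independent_of_genotype(self):
        """Null-heritability populations stay below their own permutation
        threshold in most replicates."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            pop = pdx.generate_dh_population(
                150, np.arange(0, 101, 10.0), [(50.0, 1.0)], 0.0,
                seed=int(rng.integers(2**31)))
            scan = pdx.hk_scan(pop)
            thr = pdx.permutation_threshold(pop, n_perm=200,
                                            seed=int(rng.integers(2**31)))
            hits += scan.peak_lod >= thr
        assert hits <= 4

    def test_qtl_outside_map_rejected(self):
        with pytest.raises(ValidationError):
            pdx.generate_dh_population(50, [0.0, 50.0], [(60.0, 1.0)],
                                       0.5, seed=1)

    def test_heritability_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            pdx.generate_dh_population(50, [0.0, 50.0], [], 1.2, seed=1)

    def test_genotypes_binary(self):
        pop = pdx.generate_dh_population(100, np.arange(0, 51, 5.0),
                                         [(20.0, 1.0)], 0.4, seed=6)
        assert set(np.unique(pop.genotypes)) <= {0, 1}

    def test_planted_heritability_realised(self):
        """Realised genetic variance fraction matches the requested
        heritability within sampling error."""
        pop = pdx.generate_dh_population(
            5_000, np.arange(0, 101, 5.0), [(50.0, 1.0)], 0.5, seed=7)
        g = pop.genotypes[:, 10].astype(float)  # marker at the QTL
        var_g = np.var(g * 1.0)
        h2 = var_g / np.var(pop.phenotype)
        assert h2 == pytest.approx(0.5, abs=0.05)


class TestGeneLoadSimulator:
    def test_null_table_has_no_enriched_term(self):
        loads, term = pdx.simulate_gene_loads(n_genes=50, n_terms=5, seed=1)
        assert term is None
        assert len(loads) == 50

    def test_effect_multiplies_planted_term_density(self):
        loads, term = pdx.simulate_gene_loads(
            n_genes=400, n_terms=30, enriched_effect=5.0, seed=2)
        planted = pdx.term_density(term, loads)
        others = np.mean([pdx.term_density(t, loads)
                          for g in loads for t in g.go_terms if t != term])
        assert planted > 2.5 * others
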