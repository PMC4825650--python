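"""Counting dN/dS: sites, pathway-averaged substitutions, aggregate, bootstrap."""

from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq

import parentdiff as pdx
from parentdiff.dnds import codon_path_counts, codon_sites
from parentdiff.errors import InsufficientDataError, UndefinedRatioError

from conftest import make_call


def oracle_path_counts(ref_codon, mut_codon):
    """Independent pathway enumeration using Biopython translation."""
    diffs = [i for i in range(3) if ref_codon[i] != mut_codon[i]]
    results = []
    for order in permutations(diffs):
        cur, n, s, stop = ref_codon, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + mut_codon[pos] + cur[pos + 1:]
            aa_cur = str(Seq(cur).translate())
            aa_nxt = str(Seq(nxt).translate())
            if aa_nxt == "*" and nxt != mut_codon:
                stop = True
            if aa_nxt == aa_cur:
                s += 1
            else:
                n += 1
            cur = nxt
        results.append((n, s, stop))
    valid = [r for r in results if not r[2]] or results
    return (sum(r[0] for r in valid) / len(valid),
            sum(r[1] for r in valid) / len(valid))


class TestCodonCounting:
    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            codon = "".join("ACGT"[b] for b in rng.integers(0, 4, 3))
            if str(Seq(codon).translate()) == "*":
                continue
            n, s = codon_sites(codon)
            assert n + s == pytest.approx(3.0)

    def test_fourfold_degenerate_site(self):
        n, s = codon_sites("GCT")  # Ala: third position fully synonymous
        assert s == pytest.approx(1.0)

    @pytest.mark.parametrize("ref,mut", [
        ("AAA", "AAG"), ("GCT", "CCT"), ("TTA", "CTG"), ("ATG", "CGT"),
        ("AAA", "GGA"), ("TGT", "AGA"),
    ])
    def test_pathway_average_matches_oracle(self, ref, mut):
        assert codon_path_counts(ref, mut) == pytest.approx(
            oracle_path_counts(ref, mut))


class TestGeneDnds:
    def test_no_variants_zero_rates(self, coding_rich_trio):
        m = coding_rich_trio.models[0]
        rec = pdx.gene_dnds(m, coding_rich_trio.reference, [])
        assert rec.dN == 0.0 and rec.dS == 0.0
        assert rec.n_sites + rec.s_sites == pytest.approx(3 * m.codon_count)

    def test_lysine_synonymous_example(self):
        gene = pdx.GeneModel("g", "A01", "+", [(0, 9)])
        ref = {"A01": "ATGAAATGG"}
        call = make_call(pos=5, ref="A", alt="G")  # AAA -> AAG, Lys
        rec = pdx.gene_dnds(gene, ref, [call])
        assert rec.s_subs == 1 and rec.n_subs == 0
        assert rec.dN == 0.0

    def test_premature_stop_codon_excluded(self):
        gene = pdx.GeneModel("g", "A01", "+", [(0, 9)])
        ref = {"A01": "ATGTACTGG"}
        call = make_call(pos=5, ref="C", alt="A")  # TAC -> TAA stop
        rec = pdx.gene_dnds(gene, ref, [call])
        assert rec.premature_stops == 1
        assert rec.n_subs == 0 and rec.s_subs == 0
        # excluded codon removed from the site totals too
        assert rec.n_sites + rec.s_sites == pytest.approx(6.0)

    def test_random_single_snp_genes_match_oracle(self, coding_rich_trio):
        """Counts equal an exhaustive oracle enumerating every mutational
        pathway per codon from the full mutant CDS."""
        trio = coding_rich_trio
        rng = np.random.default_rng(9)
        done = 0
        while done < 50:
            m = trio.models[rng.integers(len(trio.models))]
            s, e = m.cds_intervals[0]
            pos = int(rng.integers(s, e))
            ref_base = trio.reference[m.chromosome][pos]
            alt = "ACGT"[rng.integers(4)]
            if alt == ref_base:
                continue
            call = make_call(chrom=m.chromosome, pos=pos, ref=ref_base, alt=alt)
            rec = pdx.gene_dnds(m, trio.reference, [call])
            # oracle: rebuild mutant CDS, walk codons, enumerate pathways
            cds = m.cds_sequence(trio.reference)
            idx = m.cds_index(pos)
            alt_t = (alt if m.strand == "+"
                     else {"A": "T", "T": "A", "C": "G", "G": "C"}[alt])
            mut = cds[:idx] + alt_t + cds[idx + 1:]
            n_exp = s_exp = 0.0
            for start in range(0, len(cds), 3):
                rc, mc = cds[start:start + 3], mut[start:start + 3]
                if rc != mc:
                    if (str(Seq(mc).translate()) == "*"
                            and start + 3 < len(cds)):
                        continue
                    dn, ds = oracle_path_counts(rc, mc)
                    n_exp += dn
                    s_exp += ds
            assert rec.n_subs == pytest.approx(n_exp)
            assert rec.s_subs == pytest.approx(s_exp)
            done += 1


class TestAggregate:
    def test_neutral_records(self):
        recs = [pdx.DnDsRecord(f"g{i}", 10, 5, 1, 1, 0.03, 0.03)
                for i in range(4)]
        assert pdx.aggregate_dnds(recs) == pytest.approx(1.0)

    def test_single_record_ratio(self):
        rec = pdx.DnDsRecord("g", 10, 5, 1, 1, 0.02, 0.04)
        assert pdx.aggregate_dnds([rec]) == pytest.approx(0.5)

    def test_invariant_under_duplication(self):
        rng = np.random.default_rng(3)
        recs = [pdx.DnDsRecord(f"g{i}", 10, 5, 1, 1,
                               rng.uniform(0, 0.05), rng.uniform(0.001, 0.05))
                for i in range(20)]
        assert pdx.aggregate_dnds(recs) == pytest.approx(
            pdx.aggregate_dnds(recs + recs))

    def test_zero_mean_ds_rejected(self):
        recs = [pdx.DnDsRecord("g", 10, 5, 1, 0, 0.1, 0.0)]
        with pytest.raises(UndefinedRatioError):
            pdx.aggregate_dnds(recs)


class TestBootstrap:
    def test_identical_records_degenerate_interval(self):
        recs = [pdx.DnDsRecord(f"g{i}", 10, 5, 1, 1, 0.01, 0.02)
                for i in range(5)]
        ci = pdx.bootstrap_dnds_ci(recs, n_boot=200, seed=1)
        assert ci.lower == ci.upper == ci.point == pytest.approx(0.5)

    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(4)
        recs = [pdx.DnDsRecord(f"g{i}", 10, 5, 1, 1,
                               rng.uniform(0, 0.05), rng.uniform(0.001, 0.05))
                for i in range(30)]
        a = pdx.bootstrap_dnds_ci(recs, n_boot=500, seed=42)
        b = pdx.bootstrap_dnds_ci(recs, n_boot=500, seed=42)
        assert a == b

    def test_interval_brackets_point(self):
        rng = np.random.default_rng(5)
        recs = [pdx.DnDsRecord(f"g{i}", 10, 5, 1, 1,
                               rng.uniform(0, 0.05), rng.uniform(0.001, 0.05))
                for i in range(50)]
        ci = pdx.bootstrap_dnds_ci(recs, n_boot=1000, seed=6)
        assert ci.lower <= ci.point <= ci.upper

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(InsufficientDataError):
            pdx.bootstrap_dnds_ci(
                [pdx.DnDsRecord("g", 10, 5, 1, 1, 0.1, 0.1)], seed=0)

    def test_wider_n_boot_stabilises_endpoints(self):
        """Monte-Carlo spread of the CI endpoints across seeds shrinks when
        the number of bootstrap replicates grows tenfold."""
        rng = np.random.default_rng(8)
        recs = [pdx.DnDsRecord(f"g{i}", 10, 5, 1, 1,
                               rng.uniform(0, 0.05), rng.uniform(0.001, 0.05))
                for i in range(40)]
        lows_small = [pdx.bootstrap_dnds_ci(recs, n_boot=300, seed=s).lower
                      for s in range(12)]
        lows_big = [pdx.bootstrap_dnds_ci(recs, n_boot=3000, seed=s).lower
                    for s in range(12)]
        assert np.std(lows_big) < np.std(lows_small)


def test_purifying_regime_recovered_from_synthetic_trios():
    """Planting nonsynonymous changes at a quarter of the synonymous
    acceptance rate drives the genome aggregate below one."""
    below = 0
    for seed in range(5):
        cfg = pdx.SimulationConfig(seed=300 + seed, n_chromosomes=2,
                                   chromosome_length=80_000, n_genes=30,
                                   mutation_rate_parent1=0.01,
                                   coding_rate_scale=1.0,
                                   nonsynonymous_scale=0.25,
                                   hemi_snp_fraction=0.0)
        trio = pdx.generate_genome_trio(cfg)
        records = []
        for m in trio.models:
            inside = [c for c in trio.parent1_calls
                      if c.chromosome == m.chromosome and m.contains(c.position)]
            records.append(pdx.gene_dnds(m, trio.reference, inside))
        below += pdx.aggregate_dnds(records) < 1.0
    assert below == 5
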