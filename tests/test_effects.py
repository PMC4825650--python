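"""Effect classification, density tables, and the divergence tests."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

import parentdiff as pdx
from parentdiff.errors import (GeneModelError, InsufficientDataError,
                               ReferenceMismatchError, ValidationError)
from parentdiff.genetics import reverse_complement

from conftest import make_call


@pytest.fixture
def simple_gene():
    # ATG GCT AAA TGA on A01 at offset 10
    ref = {"A01": "N" * 10 + "ATGGCTAAATGA" + "N" * 10}
    model = pdx.GeneModel("g1", "A01", "+", [(10, 22)])
    return model, ref


class TestClassifyEffect:
    def test_third_position_synonymous(self, simple_gene):
        model, ref = simple_gene
        call = make_call(pos=15, ref="T", alt="C")  # GCT -> GCC, Ala
        assert pdx.classify_effect(call, [model], ref) == "synonymous"

    def test_first_position_nonsynonymous(self, simple_gene):
        model, ref = simple_gene
        call = make_call(pos=13, ref="G", alt="C")  # GCT -> CCT, Ala -> Pro
        assert pdx.classify_effect(call, [model], ref) == "nonsynonymous"

    def test_upstream_call_noncoding(self, simple_gene):
        model, ref = simple_gene
        call = make_call(pos=2, ref="N", alt="A")
        assert pdx.classify_effect(call, [model], ref) == "noncoding"

    def test_reference_mismatch_raises(self, simple_gene):
        model, ref = simple_gene
        call = make_call(pos=15, ref="A", alt="C")  # reference holds T
        with pytest.raises(ReferenceMismatchError):
            pdx.classify_effect(call, [model], ref)

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(GeneModelError):
            pdx.GeneModel("bad", "A01", "+", [(0, 10)])

    def test_reverse_strand_classification_matches_flipped_genome(self, trio):
        """Reverse-complementing a chromosome and flipping strand labels
        leaves every classification unchanged."""
        chrom = "A01"
        seq = trio.reference[chrom]
        L = len(seq)
        flipped_ref = dict(trio.reference, **{chrom: reverse_complement(seq)})
        models = [m for m in trio.models if m.chromosome == chrom]
        flipped_models = [
            pdx.GeneModel(m.gene_id, chrom, "-" if m.strand == "+" else "+",
                          [(L - e, L - s) for s, e in m.cds_intervals])
            for m in models]
        calls = [c for c in trio.parent1_calls if c.chromosome == chrom
                 and c.alt_frequency == 1.0][:100]
        for call in calls:
            mirrored = make_call(
                chrom=chrom, pos=L - 1 - call.position,
                ref=reverse_complement(call.ref_allele),
                alt=reverse_complement(call.alt_allele))
            assert (pdx.classify_effect(call, models, trio.reference)
                    == pdx.classify_effect(mirrored, flipped_models, flipped_ref))


def test_classification_matches_full_translation_oracle(coding_rich_trio):
    """Codon-local classification agrees with an oracle that rebuilds the
    whole mutant CDS and translates both proteins."""
    trio = coding_rich_trio
    rng = np.random.default_rng(5)
    models = list(trio.models)
    checked = 0
    while checked < 300:
        m = models[rng.integers(len(models))]
        s, e = m.cds_intervals[0]
        pos = int(rng.integers(s, e))
        ref_base = trio.reference[m.chromosome][pos]
        alt = "ACGT"[rng.integers(4)]
        if alt == ref_base:
            continue
        call = make_call(chrom=m.chromosome, pos=pos, ref=ref_base, alt=alt)
        got = pdx.classify_effect(call, [m], trio.reference)
        # oracle: substitute, rebuild, translate both full proteins
        idx = m.cds_index(pos)
        cds = m.cds_sequence(trio.reference)
        alt_t = alt if m.strand == "+" else reverse_complement(alt)
        mut = cds[:idx] + alt_t + cds[idx + 1:]
        expected = ("synonymous"
                    if str(Seq(cds).translate()) == str(Seq(mut).translate())
                    else "nonsynonymous")
        assert got == expected
        checked += 1


class TestDensity:
    def test_density_arithmetic(self):
        classified = pdx.classify_calls([], [], {})
        import pandas as pd
        classified = pd.DataFrame([
            {"chromosome": "A01", "position": i, "ref_allele": "A",
             "alt_allele": "G", "parent": "parent1", "effect": "noncoding",
             "gene_ids": ""} for i in range(10)])
        table = pdx.compute_density(classified, {"A01": 5000})
        total = table[table["category"] == "total"]["density"].iloc[0]
        assert total == pytest.approx(0.2)

    def test_no_snps_zero_density(self):
        import pandas as pd
        table = pdx.compute_density(pd.DataFrame(columns=[
            "chromosome", "position", "ref_allele", "alt_allele", "parent",
            "effect", "gene_ids"]), {"A01": 1000, "C01": 1000})
        assert (table["density"] == 0).all()

    def test_zero_callable_length_with_calls_rejected(self):
        import pandas as pd
        classified = pd.DataFrame([{"chromosome": "A01", "position": 1,
                                    "ref_allele": "A", "alt_allele": "G",
                                    "parent": "p", "effect": "noncoding",
                                    "gene_ids": ""}])
        with pytest.raises(ValidationError):
            pdx.compute_density(classified, {"A01": 0})

    def test_categories_conserved_on_trio(self, trio):
        classified = pdx.classify_calls(trio.parent1_calls, trio.models,
                                        trio.reference)
        table = pdx.compute_density(classified, trio.callable_lengths)
        for chrom, sub in table.groupby("chromosome"):
            by_cat = sub.set_index("category")["snp_count"]
            assert by_cat["total"] == (by_cat["noncoding"]
                                       + by_cat["synonymous"]
                                       + by_cat["nonsynonymous"])


class TestGenomeDensityComparison:
    def test_identical_groups(self):
        assert pdx.compare_genome_densities([2, 2, 2], [2, 2, 2]) == (0.0, 1.0)

    def test_forced_separation(self):
        rng = np.random.default_rng(0)
        a = 2 + 1e-9 * rng.standard_normal(3)
        c = 1 + 1e-9 * rng.standard_normal(3)
        _, p = pdx.compare_genome_densities(a, c)
        assert p < 0.01

    def test_matches_longhand_welch_formula(self):
        rng = np.random.default_rng(1)
        a, c = rng.normal(0.25, 0.05, 10), rng.normal(0.18, 0.07, 9)
        t, p = pdx.compare_genome_densities(a, c)
        # Welch statistic and Satterthwaite df computed longhand
        va, vc = a.var(ddof=1) / len(a), c.var(ddof=1) / len(c)
        t_exp = (a.mean() - c.mean()) / np.sqrt(va + vc)
        df = (va + vc) ** 2 / (va**2 / (len(a) - 1) + vc**2 / (len(c) - 1))
        p_exp = 2 * stats.t.sf(abs(t_exp), df)
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_single_chromosome_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            pdx.compare_genome_densities([1.0], [1.0, 2.0])


class TestEqualDivergence:
    def test_study_counts(self):
        expected, chi2, p = pdx.equal_divergence_test(355_048, 789_793)
        assert expected == 572_420.5
        assert p < 1e-4

    def test_perfect_fit(self):
        _, chi2, p = pdx.equal_divergence_test(10, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_one_sided_tail_value(self):
        _, chi2, p = pdx.equal_divergence_test(0, 20)
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            pdx.equal_divergence_test(-1, 5)
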