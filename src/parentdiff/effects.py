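"""Coding-effect classification and SNP-density tables.

A SNP is *noncoding* if it falls outside the CDS of every gene model,
otherwise *synonymous* or *nonsynonymous* by in-frame translation of the
affected codon with the standard genetic code.  Densities are percentages of
SNPs per callable base; all four categories are divided by the same callable
length, so the noncoding density is close to the total wherever coding
sequence is a small fraction of the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (GeneModelError, InsufficientDataError,
                     ReferenceMismatchError, ValidationError)
from .genetics import complement, reverse_complement, translate_codon
from .variants import VariantCall

Interval = tuple[int, int]  # 0-based half-open

EFFECT_CLASSES = ("noncoding", "synonymous", "nonsynonymous")


@dataclass
class GeneModel:
    """Single-transcript gene model giving codon context for genomic positions.

    ``cds_intervals`` are 0-based half-open genomic intervals in ascending
    genomic order; for strand ``-`` the transcript reads them right to left,
    complemented.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: list[Interval]
    go_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: bad strand {self.strand!r}")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise GeneModelError(f"{self.gene_id}: overlapping CDS intervals")
        for s, e in ivs:
            if s >= e:
                raise GeneModelError(f"{self.gene_id}: empty CDS interval ({s},{e})")
        self.cds_intervals = ivs
        if self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def codon_count(self) -> int:
        return self.cds_length // 3

    @property
    def span(self) -> Interval:
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])

    def contains(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.cds_intervals)

    def cds_index(self, position: int) -> int:
        """Transcript-orientation CDS coordinate of a genomic position."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= position < e:
                genomic_index = offset + (position - s)
                break
            offset += e - s
        else:
            raise ValidationError(
                f"position {position} not in CDS of {self.gene_id}")
        if self.strand == "+":
            return genomic_index
        return self.cds_length - 1 - genomic_index

    def cds_sequence(self, reference: Mapping[str, str] | str) -> str:
        chrom = reference if isinstance(reference, str) else reference[self.chromosome]
        seq = "".join(chrom[s:e] for s, e in self.cds_intervals)
        return reverse_complement(seq) if self.strand == "-" else seq


def _codon_change(
    model: GeneModel, reference: Mapping[str, str] | str, call: VariantCall,
) -> tuple[str, str]:
    """(reference codon, mutant codon) for a call inside the model's CDS."""
    chrom = reference if isinstance(reference, str) else reference[call.chromosome]
    if chrom[call.position].upper() != call.ref_allele.upper():
        raise ReferenceMismatchError(
            f"{call.chromosome}:{call.position} reference has "
            f"{chrom[call.position]!r}, call states {call.ref_allele!r}")
    cds = model.cds_sequence(reference)
    idx = model.cds_index(call.position)
    alt = call.alt_allele if model.strand == "+" else complement(call.alt_allele)
    codon_start = (idx // 3) * 3
    ref_codon = cds[codon_start:codon_start + 3]
    within = idx - codon_start
    mut_codon = ref_codon[:within] + alt.upper() + ref_codon[within + 1:]
    return ref_codon.upper(), mut_codon.upper()


def classify_effect(
    call: VariantCall,
    models: Iterable[GeneModel],
    reference: Mapping[str, str] | str,
) -> str:
    """Classify one SNP as noncoding / synonymous / nonsynonymous.

    A call inside the CDS of several gene models is nonsynonymous if it
    changes the protein of any of them, synonymous otherwise.
    """
    hit = [m for m in models
           if m.chromosome == call.chromosome and m.contains(call.position)]
    if not hit:
        return "noncoding"
    classes = set()
    for model in hit:
        ref_codon, mut_codon = _codon_change(model, reference, call)
        same = translate_codon(ref_codon) == translate_codon(mut_codon)
        classes.add("synonymous" if same else "nonsynonymous")
    return "nonsynonymous" if "nonsynonymous" in classes else "synonymous"


def classify_calls(
    calls: Sequence[VariantCall],
    models: Sequence[GeneModel],
    reference: Mapping[str, str] | str,
) -> pd.DataFrame:
    """Effect class for every call, with the gene(s) whose CDS it hits.

    Returns a frame with one row per call: chromosome, position, alt_allele,
    parent, effect, gene_ids (comma-joined, empty for noncoding).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    rows = []
    for call in calls:
        hit = [m for m in by_chrom.get(call.chromosome, ())
               if m.contains(call.position)]
        effect = classify_effect(call, hit, reference) if hit else "noncoding"
        rows.append({
            "chromosome": call.chromosome, "position": call.position,
            "ref_allele": call.ref_allele, "alt_allele": call.alt_allele,
            "parent": call.parent, "effect": effect,
            "gene_ids": ",".join(m.gene_id for m in hit),
        })
    return pd.DataFrame(rows, columns=["chromosome", "position", "ref_allele",
                                       "alt_allele", "parent", "effect",
                                       "gene_ids"])


def _default_genome_of(chromosome: str) -> str:
    return chromosome[0].upper()


def compute_density(
    classified: pd.DataFrame,
    callable_lengths: Mapping[str, int],
    genome_of: Callable[[str], str] = _default_genome_of,
) -> pd.DataFrame:
    """Per-chromosome SNP density table by effect category.

    ``classified`` is the output of :func:`classify_calls` (deduplicated by
    site/allele upstream if desired).  Densities are percentages of the
    chromosome's callable length; the ``total`` row is the sum of the three
    category counts.
    """
    rows = []
    for chrom, length in callable_lengths.items():
        sub = (classified[classified["chromosome"] == chrom]
               if len(classified) else classified)
        counts = {c: 0 for c in EFFECT_CLASSES}
        if len(sub):
            counts.update(sub["effect"].value_counts().to_dict())
        if length <= 0:
            if sum(counts.values()):
                raise ValidationError(
                    f"{chrom}: calls present but callable length is {length}")
            continue
        for category in EFFECT_CLASSES + ("total",):
            n = (sum(counts.values()) if category == "total"
                 else counts[category])
            rows.append({
                "chromosome": chrom, "genome": genome_of(chrom),
                "category": category, "snp_count": int(n),
                "callable_length": int(length),
                "density": 100.0 * n / length,
            })
    return pd.DataFrame(rows, columns=["chromosome", "genome", "category",
                                       "snp_count", "callable_length",
                                       "density"])


def genome_summary(density: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of per-chromosome densities by genome and category."""
    g = density.groupby(["genome", "category"])["density"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "density_mean", "std": "density_sd",
                               "count": "n_chromosomes"})


def compare_genome_densities(
    density_a: Sequence[float], density_c: Sequence[float],
) -> tuple[float, float]:
    """Welch two-sample t-test on per-chromosome densities of two genomes."""
    a = np.asarray(density_a, dtype=float)
    c = np.asarray(density_c, dtype=float)
    if len(a) < 2 or len(c) < 2:
        raise InsufficientDataError("need >= 2 chromosomes per genome")
    if np.ptp(a) == 0 and np.ptp(c) == 0 and a[0] == c[0]:
        return 0.0, 1.0  # degenerate: identical constant groups
    t, p = stats.ttest_ind(a, c, equal_var=False)
    return float(t), float(p)


def equal_divergence_test(
    count_parent1: int, count_parent2: int,
) -> tuple[float, float, float]:
    """Chi-square goodness-of-fit of two SNP totals against equal divergence.

    Returns (expected count, chi-square with 1 df, two-sided P).
    """
    if count_parent1 < 0 or count_parent2 < 0:
        raise ValidationError("counts must be nonnegative")
    if count_parent1 == 0 and count_parent2 == 0:
        raise ValidationError("both counts are zero")
    expected = (count_parent1 + count_parent2) / 2.0
    chi2 = sum((obs - expected) ** 2 / expected
               for obs in (count_parent1, count_parent2))
    p = float(stats.chi2.sf(chi2, df=1))
    return expected, float(chi2), p
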