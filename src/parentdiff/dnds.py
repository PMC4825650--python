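"""Counting estimator of dN/dS between each parent and the reference.

Per gene, SNPs are substituted into the reference CDS and synonymous /
nonsynonymous sites and substitutions are counted in the style of Nei &
Gojobori (1986): expected site counts are the per-position fractions of
possible changes that are synonymous, averaged over the two sequences, and
codons carrying several substitutions are resolved by averaging over all
minimal mutational pathways (pathways passing through a stop codon are
discarded when any stop-free pathway exists).  At within-cultivar divergences
of a few per mille, this proportion-based estimator is numerically
indistinguishable from ML codon models; an optional Jukes-Cantor correction
is provided but off by default.

The genome-wide aggregate dN̄/dS̄ is the ratio of means (mean dN over genes
divided by mean dS), with a paired bootstrap over genes for its confidence
interval: (dN, dS) pairs are resampled jointly so the gene-level coupling of
the two rates is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (InsufficientDataError, ReferenceMismatchError,
                     UndefinedRatioError, ValidationError)
from .effects import GeneModel
from .genetics import BASES, CODON_TO_AA, complement
from .variants import VariantCall


@dataclass
class DnDsRecord:
    """Per-gene substitution counts and proportion-based rates."""

    gene_id: str
    n_sites: float
    s_sites: float
    n_subs: float
    s_subs: float
    dN: float
    dS: float
    premature_stops: int = 0  # variant codons excluded as introduced stops

    @property
    def dn_defined(self) -> bool:
        return self.n_sites > 0

    @property
    def ds_defined(self) -> bool:
        return self.s_sites > 0


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap interval for the aggregate dN̄/dS̄ ratio."""

    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int
    n_redrawn: int = 0  # replicates redrawn because resampled mean dS was 0


def _syn_site_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous.

    Changes creating a stop codon count as nonsynonymous, so every position
    contributes exactly one site and sites sum to 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for base in BASES:
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1:]
        alt_aa = CODON_TO_AA[alt]
        if alt_aa == aa and alt_aa != "*":
            syn += 1
    return syn / 3.0


def codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) expected site counts for one codon."""
    s = sum(_syn_site_fraction(codon, pos) for pos in range(3))
    return 3.0 - s, s


def codon_path_counts(ref_codon: str, mut_codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) substitution counts for one codon change.

    Counts are averaged over all orderings of the changed positions; each
    single-base step is synonymous iff the amino acid is unchanged.  Orderings
    that traverse a stop codon are dropped unless every ordering does.
    """
    diffs = [i for i in range(3) if ref_codon[i] != mut_codon[i]]
    if not diffs:
        return 0.0, 0.0
    paths: list[tuple[int, int, bool]] = []  # (n steps, s steps, hits stop)
    for order in permutations(diffs):
        current = ref_codon
        n = s = 0
        hits_stop = False
        for pos in order:
            nxt = current[:pos] + mut_codon[pos] + current[pos + 1:]
            if CODON_TO_AA[nxt] == "*" and nxt != mut_codon:
                hits_stop = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                s += 1
            else:
                n += 1
            current = nxt
        paths.append((n, s, hits_stop))
    valid = [p for p in paths if not p[2]] or paths
    n_avg = sum(p[0] for p in valid) / len(valid)
    s_avg = sum(p[1] for p in valid) / len(valid)
    return n_avg, s_avg


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValidationError(f"proportion {p} too large for Jukes-Cantor")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def gene_dnds(
    gene: GeneModel,
    reference: Mapping[str, str] | str,
    variants: Sequence[VariantCall],
    jukes_cantor: bool = False,
) -> DnDsRecord:
    """Count synonymous/nonsynonymous sites and substitutions for one gene.

    ``variants`` must all fall inside the gene's CDS.  A codon whose mutant
    state is a stop codon is flagged and excluded from both site and
    substitution totals.
    """
    ref_cds = gene.cds_sequence(reference).upper()
    chrom = reference if isinstance(reference, str) else reference[gene.chromosome]

    mut = list(ref_cds)
    for call in variants:
        if not gene.contains(call.position):
            raise ValidationError(
                f"{call.chromosome}:{call.position} outside CDS of {gene.gene_id}")
        if chrom[call.position].upper() != call.ref_allele.upper():
            raise ReferenceMismatchError(
                f"{call.chromosome}:{call.position} reference has "
                f"{chrom[call.position]!r}, call states {call.ref_allele!r}")
        idx = gene.cds_index(call.position)
        alt = (call.alt_allele if gene.strand == "+"
               else complement(call.alt_allele)).upper()
        mut[idx] = alt
    mut_cds = "".join(mut)

    n_sites = s_sites = n_subs = s_subs = 0.0
    premature = 0
    for start in range(0, len(ref_cds), 3):
        ref_codon = ref_cds[start:start + 3]
        mut_codon = mut_cds[start:start + 3]
        is_last = start + 3 == len(ref_cds)
        if mut_codon != ref_codon and CODON_TO_AA[mut_codon] == "*" and not is_last:
            premature += 1
            continue
        n_ref, s_ref = codon_sites(ref_codon)
        n_mut, s_mut = codon_sites(mut_codon)
        n_sites += (n_ref + n_mut) / 2.0
        s_sites += (s_ref + s_mut) / 2.0
        if mut_codon != ref_codon:
            dn, ds = codon_path_counts(ref_codon, mut_codon)
            n_subs += dn
            s_subs += ds

    pn = n_subs / n_sites if n_sites > 0 else float("nan")
    ps = s_subs / s_sites if s_sites > 0 else float("nan")
    if jukes_cantor:
        pn = _jukes_cantor(pn) if n_sites > 0 else pn
        ps = _jukes_cantor(ps) if s_sites > 0 else ps
    return DnDsRecord(gene.gene_id, n_sites, s_sites, n_subs, s_subs,
                      dN=pn, dS=ps, premature_stops=premature)


def aggregate_dnds(records: Iterable[DnDsRecord]) -> float:
    """dN̄/dS̄ as the ratio of means over genes with defined rates."""
    recs = [r for r in records if r.dn_defined and r.ds_defined]
    if not recs:
        raise InsufficientDataError("no gene with defined dN and dS")
    mean_dn = float(np.mean([r.dN for r in recs]))
    mean_ds = float(np.mean([r.dS for r in recs]))
    if mean_ds == 0.0:
        raise UndefinedRatioError("mean dS is zero; dN̄/dS̄ undefined")
    return mean_dn / mean_ds


def bootstrap_dnds_ci(
    records: Sequence[DnDsRecord],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Paired-bootstrap percentile CI for dN̄/dS̄.

    Gene-level (dN, dS) pairs are resampled with replacement ``n_boot`` times
    and the ratio of means recomputed each time.  Replicates whose resampled
    mean dS is zero are redrawn and counted.
    """
    recs = [r for r in records if r.dn_defined and r.ds_defined]
    if len(recs) < 2:
        raise InsufficientDataError("paired bootstrap needs >= 2 genes")
    dn = np.array([r.dN for r in recs])
    ds = np.array([r.dS for r in recs])
    point = aggregate_dnds(recs)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(recs), size=(n_boot, len(recs)))
    mean_dn = dn[idx].mean(axis=1)
    mean_ds = ds[idx].mean(axis=1)
    n_redrawn = 0
    bad = mean_ds == 0.0
    while bad.any():
        n_redrawn += int(bad.sum())
        redo = rng.integers(0, len(recs), size=(int(bad.sum()), len(recs)))
        mean_dn[bad] = dn[redo].mean(axis=1)
        mean_ds[bad] = ds[redo].mean(axis=1)
        bad = mean_ds == 0.0
    ratios = mean_dn / mean_ds
    alpha = 1.0 - level
    lower, upper = np.quantile(ratios, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapCI(point=point, lower=float(lower), upper=float(upper),
                       n_boot=n_boot, seed=seed, n_redrawn=n_redrawn)
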