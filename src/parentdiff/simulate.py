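"""Synthetic genome trios, GO tables and DH populations with known truth.

The generator emulates everything downstream of read alignment in a
two-parent resequencing design: a reference genome with single-transcript
gene models, two inbred parents diverged from it at controlled coding and
noncoding rates (partly through a shared ancestral pool so the
"both-parents-vs-reference" list is populated), hemi-SNP artifacts from a
duplicated donor segment, a focal insertion in one flowering gene, GO
annotation tables with one planted enriched term, and doubled-haploid
populations segregating planted QTL on a Kosambi map.

All randomness flows from one ``numpy.random.default_rng(seed)``; the same
configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .effects import GeneModel
from .errors import SizingError, ValidationError
from .genetics import STOP_CODONS, reverse_complement
from .qtl import DhPopulation
from .variants import VariantCall

_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study design.

    Rates are per-site probabilities of divergence from the reference;
    ``coding_rate_scale`` multiplies them inside CDS, and
    ``nonsynonymous_scale`` further thins amino-acid-changing plantings so
    the default regime is purifying (dN/dS < 1).  ``shared_fraction`` of
    the smaller parent rate is drawn from a pool common to both parents,
    and C-subgenome chromosomes diverge at ``c_genome_rate_scale`` times
    the A-subgenome rate, mirroring the lower C-genome diversity of the
    amphidiploid.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 200_000
    n_genes: int = 60
    mean_cds_length: int = 300          # codons
    mutation_rate_parent1: float = 0.006
    mutation_rate_parent2: float = 0.004
    coding_rate_scale: float = 0.5
    ts_tv_ratio: float = 2.0
    hemi_snp_fraction: float = 0.10
    focal_indel_length: int = 5624
    go_terms: int = 40
    enriched_term_effect: float = 5.0
    callable_fraction: float = 0.82
    nonsynonymous_scale: float = 0.5
    shared_fraction: float = 0.3
    c_genome_rate_scale: float = 0.7

    def validate(self) -> None:
        probs = dict(mutation_rate_parent1=self.mutation_rate_parent1,
                     mutation_rate_parent2=self.mutation_rate_parent2,
                     coding_rate_scale=self.coding_rate_scale,
                     hemi_snp_fraction=self.hemi_snp_fraction,
                     callable_fraction=self.callable_fraction,
                     nonsynonymous_scale=self.nonsynonymous_scale,
                     shared_fraction=self.shared_fraction,
                     c_genome_rate_scale=self.c_genome_rate_scale)
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}={value} outside [0, 1]")
        counts = dict(n_chromosomes=self.n_chromosomes,
                      chromosome_length=self.chromosome_length,
                      n_genes=self.n_genes,
                      mean_cds_length=self.mean_cds_length,
                      go_terms=self.go_terms,
                      focal_indel_length=self.focal_indel_length)
        for name, value in counts.items():
            if value <= 0:
                raise ValidationError(f"{name}={value} must be positive")
        if self.ts_tv_ratio < 0:
            raise ValidationError("ts_tv_ratio must be nonnegative")
        if self.hemi_snp_fraction >= 1.0:
            raise ValidationError("hemi_snp_fraction must be < 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated trio.

    ``planted_variants`` rows are (chromosome, position, parent, ref, alt,
    effect_class) with parent in {parent1, parent2, both};
    ``hemi_artifacts`` rows are (chromosome, position, parent, alt).
    """

    planted_variants: list[tuple[str, int, str, str, str, str]]
    planted_indel: tuple[str, int, int]
    enriched_term: str
    dh_qtl: list[tuple[str, float, float]] = field(default_factory=list)
    hemi_artifacts: list[tuple[str, int, str, str]] = field(default_factory=list)

    def variants_of(self, parent: str) -> list[tuple[str, int, str, str, str, str]]:
        return [v for v in self.planted_variants if v[2] in (parent, "both")]


@dataclass
class GenomeTrio:
    """Reference + two parent call sets with truth and annotations."""

    reference: dict[str, str]
    models: list[GeneModel]
    parent1_calls: list[VariantCall]
    parent2_calls: list[VariantCall]
    truth: SyntheticTruth
    callable_intervals: dict[str, list[tuple[int, int]]]
    go_table: list[tuple[str, str]]        # (gene_id, term_id)
    term_names: dict[str, str]

    @property
    def callable_lengths(self) -> dict[str, int]:
        return {c: sum(e - s for s, e in ivs)
                for c, ivs in self.callable_intervals.items()}


_KEYWORD_TERMS = [
    "flower development (synthetic)",
    "root morphogenesis (synthetic)",
    "regulation of vernalization response (synthetic)",
    "lateral root formation (synthetic)",
    "floral organ identity (synthetic)",
]


def _term_catalogue(n_terms: int, enriched_index: int) -> dict[str, str]:
    names = {}
    for i in range(n_terms):
        term = f"GO:{i + 1:07d}"
        if i < len(_KEYWORD_TERMS):
            names[term] = _KEYWORD_TERMS[i]
        elif i == enriched_index:
            names[term] = "response to gibberellin stimulus (synthetic)"
        else:
            names[term] = f"metabolic process variant {i + 1} (synthetic)"
    return names


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal non-stop codons + one stop codon."""
    internal = []
    while len(internal) < n_codons - 2:
        codon = "".join("ACGT"[b] for b in rng.integers(0, 4, 3))
        if codon not in STOP_CODONS:
            internal.append(codon)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(internal) + stop


def _place_genes(
    rng: np.random.Generator,
    config: SimulationConfig,
    chrom_names: list[str],
    chrom_arrays: dict[str, np.ndarray],
) -> list[GeneModel]:
    """Evenly slotted single-transcript genes, ~30% two-exon, mixed strand."""
    per_chrom = np.full(len(chrom_names), config.n_genes // len(chrom_names))
    per_chrom[: config.n_genes % len(chrom_names)] += 1
    models: list[GeneModel] = []
    gene_no = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        if n_here == 0:
            continue
        slot = config.chromosome_length // int(n_here)
        for k in range(int(n_here)):
            codons = max(30, int(rng.normal(config.mean_cds_length,
                                            config.mean_cds_length / 4)))
            cds_len = 3 * codons
            intron = int(rng.integers(80, 300)) if rng.random() < 0.3 else 0
            span = cds_len + intron
            margin = slot - span - 200
            if margin <= 0:
                raise SizingError(
                    f"{chrom}: slot of {slot} bp cannot host a {span} bp gene; "
                    "increase chromosome_length or reduce n_genes/mean_cds_length")
            start = k * slot + 100 + int(rng.integers(0, margin))
            if intron:
                exon1 = 3 * int(rng.integers(10, codons - 10))
                intervals = [(start, start + exon1),
                             (start + exon1 + intron, start + span)]
            else:
                intervals = [(start, start + span)]
            strand = "+" if rng.random() < 0.5 else "-"
            cds = _random_cds(rng, codons)
            genomic = cds if strand == "+" else reverse_complement(cds)
            offset = 0
            for s, e in intervals:
                piece = genomic[offset:offset + (e - s)]
                chrom_arrays[chrom][s:e] = np.frombuffer(
                    piece.encode("ascii"), dtype=np.uint8)
                offset += e - s
            gene_no += 1
            models.append(GeneModel(
                gene_id=f"gene{gene_no:04d}", chromosome=chrom,
                strand=strand, cds_intervals=intervals))
    return models


def _callable_intervals(
    rng: np.random.Generator,
    length: int,
    fraction: float,
    gene_spans: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Complement of a few uncallable gaps placed outside gene bodies."""
    gap_total = int(round((1.0 - fraction) * length))
    if gap_total == 0:
        return [(0, length)]
    n_gaps = min(5, max(1, gap_total // 2000))
    sizes = np.full(n_gaps, gap_total // n_gaps)
    sizes[: gap_total % n_gaps] += 1
    gaps: list[tuple[int, int]] = []
    for size in sizes:
        for _ in range(100):
            start = int(rng.integers(0, max(1, length - int(size))))
            cand = (start, start + int(size))
            clash = any(s < cand[1] and cand[0] < e for s, e in gene_spans)
            clash = clash or any(s < cand[1] and cand[0] < e for s, e in gaps)
            if not clash:
                gaps.append(cand)
                break
        else:  # crowded chromosome: allow overlap with genes
            gaps.append((start, start + int(size)))
    gaps.sort()
    callable_ivs, cursor = [], 0
    for s, e in gaps:
        if cursor < s:
            callable_ivs.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        callable_ivs.append((cursor, length))
    return callable_ivs


def _truth_effect(model: GeneModel, reference: Mapping[str, str],
                  position: int, alt: str) -> str:
    """Effect class by rebuilding the mutant CDS and translating both."""
    ref_cds = model.cds_sequence(reference)
    idx = model.cds_index(position)
    alt_t = alt if model.strand == "+" else reverse_complement(alt)
    mut_cds = ref_cds[:idx] + alt_t + ref_cds[idx + 1:]
    same = str(Seq(ref_cds).translate()) == str(Seq(mut_cds).translate())
    return "synonymous" if same else "nonsynonymous"


def _choose_alts(rng: np.random.Generator, refs: np.ndarray,
                 ts_tv_ratio: float) -> list[str]:
    """Alternate alleles at given reference bases under a ts/tv ratio."""
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0) if ts_tv_ratio > 0 else 0.0
    alts = []
    for ref in refs:
        ref = chr(ref) if isinstance(ref, (int, np.integer)) else ref
        if rng.random() < p_ts:
            alts.append(_TRANSITION[ref])
        else:
            tv = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
            alts.append(tv[int(rng.integers(0, 2))])
    return alts


def _emit_call(rng: np.random.Generator, chrom: str, pos: int, ref: str,
               alt: str, parent: str, hemi: bool) -> VariantCall:
    af = float(rng.uniform(0.25, 0.75)) if hemi else 1.0
    return VariantCall(
        chromosome=chrom, position=int(pos), ref_allele=ref, alt_allele=alt,
        quality=float(30.0 + rng.gamma(3.0, 5.0)),
        depth=int(5 + rng.poisson(20)),
        alt_frequency=af,
        prob_not_ref=float(0.90 + 0.10 * rng.random()),
        parent=parent)


def generate_genome_trio(config: SimulationConfig) -> GenomeTrio:
    """Reference + gene models + two parent call sets with planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_a = (config.n_chromosomes + 1) // 2
    chrom_names = ([f"A{i + 1:02d}" for i in range(n_a)]
                   + [f"C{i + 1:02d}" for i in range(config.n_chromosomes - n_a)])
    chrom_arrays = {c: _BASES_U8[rng.integers(0, 4, config.chromosome_length)]
                    for c in chrom_names}
    models = _place_genes(rng, config, chrom_names, chrom_arrays)
    reference = {c: a.tobytes().decode("ascii") for c, a in chrom_arrays.items()}

    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chrom_names}
    for m in models:
        by_chrom[m.chromosome].append(m)
    gene_starts = {c: [m.span[0] for m in ms] for c, ms in by_chrom.items()}

    callable_intervals = {
        c: _callable_intervals(rng, config.chromosome_length,
                               config.callable_fraction,
                               [m.span for m in by_chrom[c]])
        for c in chrom_names}
    callable_mask = {}
    coding_mask = {}
    for c in chrom_names:
        mask = np.zeros(config.chromosome_length, dtype=bool)
        for s, e in callable_intervals[c]:
            mask[s:e] = True
        callable_mask[c] = mask
        cmask = np.zeros(config.chromosome_length, dtype=bool)
        for m in by_chrom[c]:
            for s, e in m.cds_intervals:
                cmask[s:e] = True
        coding_mask[c] = cmask

    # GO annotation: 1-4 random terms per gene; one designated enriched term
    enriched_index = min(config.go_terms - 1, len(_KEYWORD_TERMS))
    term_names = _term_catalogue(config.go_terms, enriched_index)
    term_ids = sorted(term_names)
    enriched_term = f"GO:{enriched_index + 1:07d}"
    n_enriched_genes = max(2, config.n_genes // 10)
    enriched_genes = set(rng.choice([m.gene_id for m in models],
                                    size=n_enriched_genes, replace=False))
    go_table: list[tuple[str, str]] = []
    for m in models:
        k = int(rng.integers(1, 5))
        picks = set(rng.choice(term_ids, size=k, replace=False))
        picks.discard(enriched_term)
        if m.gene_id in enriched_genes:
            picks.add(enriched_term)
        if not picks:
            picks.add(term_ids[int(rng.integers(0, len(term_ids)))])
        m.go_terms = frozenset(picks)
        go_table.extend((m.gene_id, t) for t in sorted(picks))

    def model_at(chrom: str, pos: int) -> GeneModel | None:
        ms = by_chrom[chrom]
        i = bisect_right(gene_starts[chrom], pos) - 1
        if i >= 0 and ms[i].contains(pos):
            return ms[i]
        return None

    shared_rate = config.shared_fraction * min(config.mutation_rate_parent1,
                                               config.mutation_rate_parent2)
    pools = [("both", shared_rate),
             ("parent1", config.mutation_rate_parent1 - shared_rate),
             ("parent2", config.mutation_rate_parent2 - shared_rate)]

    planted: list[tuple[str, int, str, str, str, str]] = []
    used: dict[str, set[int]] = {c: set() for c in chrom_names}
    for c in chrom_names:
        seq = reference[c]
        chrom_scale = (config.c_genome_rate_scale if c.startswith("C")
                       else 1.0)
        base_rate = np.zeros(config.chromosome_length)
        for parent, rate in pools:
            rate = rate * chrom_scale
            if rate <= 0:
                continue
            base_rate[:] = rate
            base_rate[coding_mask[c]] = rate * config.coding_rate_scale
            base_rate[~callable_mask[c]] = 0.0
            positions = np.nonzero(rng.random(config.chromosome_length)
                                   < base_rate)[0]
            refs = np.array([seq[p] for p in positions])
            alts = _choose_alts(rng, refs, config.ts_tv_ratio)
            for pos, ref, alt in zip(positions, refs, alts):
                pos = int(pos)
                if pos in used[c]:
                    continue
                model = model_at(c, pos) if coding_mask[c][pos] else None
                if model is None:
                    effect = "noncoding"
                else:
                    effect = _truth_effect(model, reference, pos, alt)
                    if (effect == "nonsynonymous"
                            and rng.random() > config.nonsynonymous_scale):
                        continue
                used[c].add(pos)
                planted.append((c, pos, parent, str(ref), alt, effect))

        # extra nonsynonymous load in enriched-term genes
        extra = (config.mutation_rate_parent1 * chrom_scale
                 * config.coding_rate_scale
                 * max(0.0, config.enriched_term_effect - 1.0))
        if extra > 0:
            for m in by_chrom[c]:
                if m.gene_id not in enriched_genes:
                    continue
                for s, e in m.cds_intervals:
                    hits = np.nonzero(rng.random(e - s) < extra)[0] + s
                    for pos in hits:
                        pos = int(pos)
                        if pos in used[c] or not callable_mask[c][pos]:
                            continue
                        ref = seq[pos]
                        choices = [b for b in "ACGT" if b != ref]
                        rng.shuffle(choices)
                        for alt in choices:
                            if _truth_effect(m, reference, pos, alt) == "nonsynonymous":
                                break
                        else:
                            continue
                        if rng.random() > config.nonsynonymous_scale:
                            continue
                        used[c].add(pos)
                        planted.append((c, pos, "parent1", ref, alt,
                                        "nonsynonymous"))

    planted.sort()

    # hemi-SNP artifacts: heterozygous-looking calls inside one duplicated
    # donor segment per chromosome
    h = config.hemi_snp_fraction
    hemi_truth: list[tuple[str, int, str, str]] = []
    hemi_calls: dict[str, list[VariantCall]] = {"parent1": [], "parent2": []}
    if h > 0:
        seg_len = max(1000, config.chromosome_length // 10)
        segments = {}
        for c in chrom_names:
            s = int(rng.integers(0, config.chromosome_length - seg_len))
            segments[c] = (s, s + seg_len)
        for parent in ("parent1", "parent2"):
            n_real = sum(1 for v in planted if v[2] in (parent, "both"))
            n_hemi = int(round(h / (1.0 - h) * n_real))
            for _ in range(n_hemi):
                c = chrom_names[int(rng.integers(0, len(chrom_names)))]
                s, e = segments[c]
                for _try in range(50):
                    pos = int(rng.integers(s, e))
                    if pos not in used[c] and callable_mask[c][pos]:
                        break
                else:
                    continue
                used[c].add(pos)
                ref = reference[c][pos]
                alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
                hemi_truth.append((c, pos, parent, alt))
                hemi_calls[parent].append(
                    _emit_call(rng, c, pos, ref, alt, parent, hemi=True))

    parent1_calls = [
        _emit_call(rng, c, p, ref, alt, "parent1", hemi=False)
        for (c, p, parent, ref, alt, _eff) in planted if parent in ("parent1", "both")
    ] + hemi_calls["parent1"]
    parent2_calls = [
        _emit_call(rng, c, p, ref, alt, "parent2", hemi=False)
        for (c, p, parent, ref, alt, _eff) in planted if parent in ("parent2", "both")
    ] + hemi_calls["parent2"]
    parent1_calls.sort(key=lambda v: v.key)
    parent2_calls.sort(key=lambda v: v.key)

    # focal insertion: first exon of a flowering-annotated gene on an A chromosome
    flower_terms = {t for t, name in term_names.items()
                    if "flower" in name or "floral" in name}
    focal = next((m for m in models
                  if m.chromosome.startswith("A") and (m.go_terms & flower_terms)),
                 models[0])
    indel = (focal.gene_id,
             focal.cds_intervals[0][0] + 30,
             config.focal_indel_length)

    truth = SyntheticTruth(planted_variants=planted, planted_indel=indel,
                           enriched_term=enriched_term,
                           hemi_artifacts=sorted(hemi_truth))
    return GenomeTrio(reference=reference, models=models,
                      parent1_calls=parent1_calls, parent2_calls=parent2_calls,
                      truth=truth, callable_intervals=callable_intervals,
                      go_table=go_table, term_names=term_names)


def generate_dh_population(
    n_lines: int,
    marker_map: Sequence[float],
    qtl: Sequence[tuple[float, float]],
    heritability: float,
    seed: int,
    chromosome: str = "A10",
    marker_ids: Sequence[str] | None = None,
) -> DhPopulation:
    """Doubled-haploid population segregating planted QTL.

    Genotypes follow a Markov chain along the map with Kosambi-implied
    recombination fractions between adjacent loci; the phenotype is the sum
    of QTL effects plus Gaussian noise scaled so the planted QTL explain
    ``heritability`` of the phenotypic variance (heritability 0 gives pure
    noise, independent of genotype).
    """
    positions = np.asarray(marker_map, dtype=float)
    if len(positions) < 2 or np.any(np.diff(positions) < 0):
        raise ValidationError("marker map must be non-decreasing, >= 2 markers")
    if not 0.0 <= heritability <= 1.0:
        raise ValidationError("heritability must lie in [0, 1]")
    for pos_q, _eff in qtl:
        if not positions[0] <= pos_q <= positions[-1]:
            raise ValidationError(
                f"QTL at {pos_q} cM outside map span "
                f"[{positions[0]}, {positions[-1]}]")

    rng = np.random.default_rng(seed)
    qtl_pos = [float(p) for p, _ in qtl]
    all_pos = np.unique(np.concatenate([positions, np.asarray(qtl_pos)]))
    rfs = _kosambi_vec(np.diff(all_pos))

    geno = np.empty((n_lines, len(all_pos)), dtype=np.int8)
    geno[:, 0] = rng.integers(0, 2, n_lines)
    for j, r in enumerate(rfs):
        switch = rng.random(n_lines) < r
        geno[:, j + 1] = geno[:, j] ^ switch

    col_of = {float(p): j for j, p in enumerate(all_pos)}
    genetic = np.zeros(n_lines)
    for pos_q, effect in qtl:
        genetic += float(effect) * geno[:, col_of[float(pos_q)]]

    if heritability == 0.0 or not qtl:
        phenotype = rng.standard_normal(n_lines)
    else:
        var_g = float(np.var(genetic))
        if var_g == 0.0:
            phenotype = genetic + rng.standard_normal(n_lines)
        elif heritability == 1.0:
            phenotype = genetic.copy()
        else:
            sigma_e = np.sqrt(var_g * (1.0 - heritability) / heritability)
            phenotype = genetic + rng.normal(0.0, sigma_e, n_lines)

    marker_cols = [col_of[float(p)] for p in positions]
    ids = (list(marker_ids) if marker_ids is not None
           else [f"M{i + 1:03d}" for i in range(len(positions))])
    return DhPopulation(marker_ids=ids, positions_cM=positions,
                        genotypes=geno[:, marker_cols],
                        phenotype=phenotype, chromosome=chromosome)


def _kosambi_vec(d_cM: np.ndarray) -> np.ndarray:
    e = np.exp(4.0 * np.asarray(d_cM, dtype=float) / 100.0)
    return (e - 1.0) / (2.0 * (e + 1.0))


def simulate_gene_loads(
    n_genes: int = 500,
    n_terms: int = 50,
    mean_codons: int = 300,
    ns_rate_per_codon: float = 0.01,
    enriched_effect: float | None = None,
    enriched_n_genes: int = 20,
    seed: int = 0,
):
    """Gene-load table for enrichment testing, optionally with a planted term.

    Returns ``(loads, enriched_term)``; ``enriched_term`` is None for null
    tables.  Under the null, each gene's nonsynonymous count is Poisson with
    mean proportional to its codon count, so no term is truly enriched.
    """
    from .enrichment import GeneLoad

    rng = np.random.default_rng(seed)
    codons = np.maximum(50, rng.poisson(mean_codons, n_genes))
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    members: dict[str, set[int]] = {}
    for t in term_ids[1:]:
        size = int(rng.integers(5, 41))
        members[t] = set(rng.choice(n_genes, size=min(size, n_genes),
                                    replace=False).tolist())
    enriched_term = None
    rate = np.full(n_genes, ns_rate_per_codon)
    first = set(rng.choice(n_genes, size=min(enriched_n_genes, n_genes),
                           replace=False).tolist())
    members[term_ids[0]] = first
    if enriched_effect is not None:
        enriched_term = term_ids[0]
        rate[list(first)] *= enriched_effect
    ns = rng.poisson(rate * codons)
    loads = []
    for g in range(n_genes):
        terms = frozenset(t for t, mem in members.items() if g in mem)
        loads.append(GeneLoad(f"gene{g + 1:04d}", int(ns[g]), int(codons[g]),
                              terms))
    return loads, enriched_term


def make_genome_with_duplication(
    length: int = 20_000,
    dup_length: int = 2_000,
    seed: int = 0,
    name: str = "chr1",
) -> dict[str, str]:
    """Random genome with one internal duplicated block (for multimap tests)."""
    rng = np.random.default_rng(seed)
    arr = _BASES_U8[rng.integers(0, 4, length)]
    src = int(rng.integers(0, length // 2 - dup_length))
    dst = int(rng.integers(length // 2, length - dup_length))
    arr[dst:dst + dup_length] = arr[src:src + dup_length]
    return {name: arr.tobytes().decode("ascii")}


def sample_reads(
    genome: Mapping[str, str],
    n_reads: int,
    read_length: int = 100,
    seed: int = 0,
) -> list[str]:
    """Error-free reads sampled uniformly from both strands of a genome."""
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) - read_length + 1 for c in chroms])
    if np.any(lengths <= 0):
        raise ValidationError("genome shorter than read length")
    probs = lengths / lengths.sum()
    reads = []
    for _ in range(n_reads):
        c = chroms[int(rng.choice(len(chroms), p=probs))]
        start = int(rng.integers(0, len(genome[c]) - read_length + 1))
        read = genome[c][start:start + read_length]
        if rng.random() < 0.5:
            read = reverse_complement(read)
        reads.append(read)
    return reads
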