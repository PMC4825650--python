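"""Per-parent call filtering, hemi-SNP exclusion and the three-list comparison.

Both inbred parents were called against the same reference, so a site can be
(i) divergent from the reference in both parents with the same allele, or
(ii) called in only one parent.  Calls in class (ii) are the polymorphisms
that actually segregate between the parents.  Apparent heterozygous calls in
an inbred ("hemi-SNPs", reads from a homeologous locus mapping to the wrong
subgenome) are excluded before the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ReferenceMismatchError, ValidationError

#: identity of a call for set comparisons
Key = tuple[str, int, str]


@dataclass(frozen=True)
class VariantCall:
    """One called substitution with its filtering evidence.

    Positions are 0-based.  ``alt_frequency`` is the fraction of reads
    supporting the alternate allele; ``prob_not_ref`` is the caller's
    probability that the base differs from the reference (0-1 scale).
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    quality: float
    depth: int
    alt_frequency: float
    prob_not_ref: float
    parent: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"{self.chromosome}:{self.position} ref==alt ({self.ref_allele})")
        if not 0.0 <= self.alt_frequency <= 1.0:
            raise ValidationError(
                f"{self.chromosome}:{self.position} alt_frequency "
                f"{self.alt_frequency} outside [0, 1]")
        if not 0.0 <= self.prob_not_ref <= 1.0:
            raise ValidationError(
                f"{self.chromosome}:{self.position} prob_not_ref "
                f"{self.prob_not_ref} outside [0, 1]")
        if self.depth < 0:
            raise ValidationError(
                f"{self.chromosome}:{self.position} negative depth {self.depth}")

    @property
    def key(self) -> Key:
        return (self.chromosome, self.position, self.alt_allele)


@dataclass
class ComparisonResult:
    """Three-list comparison of two parents' reference-based call sets."""

    shared_vs_reference: list[VariantCall]
    parent1_only: list[VariantCall]
    parent2_only: list[VariantCall]
    hemi_snps_excluded: list[VariantCall] = field(default_factory=list)

    @property
    def polymorphic_between_parents(self) -> list[VariantCall]:
        """Calls present in exactly one parent: the segregating set."""
        return self.parent1_only + self.parent2_only


@dataclass(frozen=True)
class AccuracyEstimate:
    """Empirical call accuracy from manual review of a random subset."""

    n_reviewed: int
    n_confirmed: int

    def __post_init__(self) -> None:
        if self.n_reviewed <= 0:
            raise ValidationError("n_reviewed must be positive")
        if not 0 <= self.n_confirmed <= self.n_reviewed:
            raise ValidationError(
                f"n_confirmed {self.n_confirmed} outside [0, {self.n_reviewed}]")

    @property
    def accuracy(self) -> float:
        return self.n_confirmed / self.n_reviewed

    @property
    def percent(self) -> float:
        """Accuracy as a percentage rounded to one decimal for display."""
        return round(100.0 * self.accuracy, 1)

    def corrected_count(self, raw_count: float) -> float:
        """Scale a raw genome-wide call count by the estimated accuracy."""
        return raw_count * self.accuracy


_REQUIRED = ("quality", "alt_frequency", "depth", "prob_not_ref")


def filter_calls(
    calls: Iterable[VariantCall],
    min_quality: float = 30.0,
    min_frequency: float = 0.05,
    min_depth: int = 5,
    min_prob_not_ref: float = 0.90,
) -> list[VariantCall]:
    """Keep calls meeting all four evidence thresholds, each inclusive (>=).

    Defaults are the study filter: Phred quality >= 30, alternate-allele
    frequency >= 5%, depth >= 5, probability-not-reference >= 0.90.
    """
    kept = []
    for call in calls:
        for name in _REQUIRED:
            if getattr(call, name) is None:
                raise ValidationError(
                    f"call {call.chromosome}:{call.position} missing field {name!r}")
        if (call.quality >= min_quality
                and call.alt_frequency >= min_frequency
                and call.depth >= min_depth
                and call.prob_not_ref >= min_prob_not_ref):
            kept.append(call)
    return kept


def flag_hemi_snps(
    calls: Iterable[VariantCall],
    het_band: tuple[float, float] = (0.2, 0.8),
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (clean, hemi) by allele frequency.

    A call whose alternate-allele frequency lies strictly inside ``het_band``
    looks heterozygous, which in a fully inbred line indicates reads from a
    homeologous locus rather than a real variant.
    """
    low, high = het_band
    if not 0.0 <= low < high <= 1.0:
        raise ValidationError(f"invalid het band {het_band}")
    clean, hemi = [], []
    for call in calls:
        (hemi if low < call.alt_frequency < high else clean).append(call)
    return clean, hemi


def compare_parents(
    parent1: Sequence[VariantCall],
    parent2: Sequence[VariantCall],
) -> ComparisonResult:
    """Derive the three lists: shared-vs-reference and each parent-only set.

    Identity is (chromosome, position, alt allele); two parents carrying
    different alternate alleles at one site yield two parent-only records.
    A site present in both parents with conflicting *reference* alleles is a
    data inconsistency and raises :class:`ReferenceMismatchError`.
    """
    by_key1 = {c.key: c for c in parent1}
    by_key2 = {c.key: c for c in parent2}

    ref_at: dict[tuple[str, int], str] = {}
    for call in list(by_key1.values()) + list(by_key2.values()):
        site = (call.chromosome, call.position)
        seen = ref_at.setdefault(site, call.ref_allele)
        if seen != call.ref_allele:
            raise ReferenceMismatchError(
                f"{call.chromosome}:{call.position} reference allele conflict "
                f"({seen} vs {call.ref_allele})")

    shared = [by_key1[k] for k in sorted(by_key1.keys() & by_key2.keys())]
    only1 = [by_key1[k] for k in sorted(by_key1.keys() - by_key2.keys())]
    only2 = [by_key2[k] for k in sorted(by_key2.keys() - by_key1.keys())]
    return ComparisonResult(shared, only1, only2)


def estimate_accuracy(n_reviewed: int, n_confirmed: int) -> AccuracyEstimate:
    """Accuracy of the automated caller from manually reviewed sites."""
    return AccuracyEstimate(n_reviewed=n_reviewed, n_confirmed=n_confirmed)
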