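"""Read multi-mapping profiler for toy genomes.

Counts, for each short read, the number of genomic loci (distinct start
positions, both strands) where the read aligns within an edit-distance
budget, and summarises the per-read counts as a histogram.  On 100 bp reads
the default budget of 5 substitutions coincides with a 95% identity
threshold.  Hamming distance (substitutions only) is the default; a gapped
Levenshtein mode backed by edlib is available.  This is a desk-scale
profiler for genomes up to a few Mbp, not a production aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np

from .errors import ValidationError
from .genetics import reverse_complement

_ENCODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Sequence as a uint8 array (A=0 C=1 G=2 T=3)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class HitProfile:
    """Distribution of per-read hit counts across a read set."""

    per_read_hits: np.ndarray
    max_reported: int

    @property
    def histogram(self) -> dict[int, int]:
        values, counts = np.unique(self.per_read_hits, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    @property
    def median_hits(self) -> float:
        return float(np.median(self.per_read_hits))

    @property
    def n_capped(self) -> int:
        """Reads whose hit count was truncated at the reporting cap."""
        return int((self.per_read_hits >= self.max_reported).sum())


def _hamming_mask(read: np.ndarray, chrom: np.ndarray, max_edit: int) -> np.ndarray:
    """Boolean mask over start positions where <= max_edit substitutions
    align read to chrom.

    Mismatch counts are accumulated incrementally across read offsets, one
    vectorised comparison per read position.
    """
    n_windows = len(chrom) - len(read) + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=bool)
    mismatches = np.zeros(n_windows, dtype=np.int32)
    for j in range(len(read)):
        mismatches += chrom[j:j + n_windows] != read[j]
    return mismatches <= max_edit


def _levenshtein_starts(read: str, chrom: str, max_edit: int) -> set[int]:
    """Distinct alignment start locations with edit distance <= max_edit."""
    res = edlib.align(read, chrom, mode="HW", task="locations", k=max_edit)
    if res["editDistance"] < 0:
        return set()
    return {loc[0] for loc in res["locations"]}


def count_hits(
    read: str,
    genome: Mapping[str, str],
    max_edit: int = 5,
    max_report: int = 500,
    mode: str = "hamming",
) -> int:
    """Number of genomic loci matching ``read`` within the edit budget.

    A locus is a distinct start position on the reference where either the
    read or its reverse complement aligns, so palindromic reads are not
    double-counted.  The count is capped at ``max_report`` (the aligner's
    reporting cap for secondary alignments).
    """
    if not genome:
        raise ValidationError("empty genome")
    if len(read) < 1:
        raise ValidationError("empty read")
    if max_edit < 0:
        raise ValidationError("max_edit must be >= 0")
    rc = reverse_complement(read)
    total = 0
    for seq in genome.values():
        if mode == "hamming":
            enc = encode(seq)
            hit = (_hamming_mask(encode(read), enc, max_edit)
                   | _hamming_mask(encode(rc), enc, max_edit))
            total += int(hit.sum())
        elif mode == "levenshtein":
            total += len(_levenshtein_starts(read, seq, max_edit)
                         | _levenshtein_starts(rc, seq, max_edit))
        else:
            raise ValidationError(f"unknown mode {mode!r}")
        if total >= max_report:
            return max_report
    return total


def profile(
    reads: Sequence[str],
    genome: Mapping[str, str],
    max_edit: int = 5,
    max_report: int = 500,
    mode: str = "hamming",
) -> HitProfile:
    """Hit-count profile over a read set (histogram, median, cap flags)."""
    if not reads:
        raise ValidationError("no reads")
    hits = np.array([count_hits(r, genome, max_edit, max_report, mode)
                     for r in reads], dtype=np.int64)
    return HitProfile(per_read_hits=hits, max_reported=max_report)
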