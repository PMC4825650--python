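"""Haley-Knott regression QTL scanning for doubled-haploid populations.

A DH line is fully homozygous, so genotypes are coded {0, 1} and single-QTL
interval mapping reduces to regressing the phenotype on the conditional
probability of the parent-1 allele at each grid position given the flanking
typed markers.  Map distances use the Kosambi function,
d = 25 ln((1+2r)/(1-2r)) cM, whose interference model matches the genetic
maps the populations were built on.  LOD = (n/2) log10(RSS0/RSS1).
Genome-wide significance comes from permuting the phenotype vector against
the genotype rows and taking the (1-alpha) quantile of the per-permutation
maximum LOD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError

MISSING = -1  # genotype code for untyped marker


@dataclass
class DhPopulation:
    """Marker map, genotype matrix and phenotype for one chromosome."""

    marker_ids: list[str]
    positions_cM: np.ndarray
    genotypes: np.ndarray  # n_lines x n_markers, int8 over {0, 1, MISSING}
    phenotype: np.ndarray
    chromosome: str = "1"

    def __post_init__(self) -> None:
        self.positions_cM = np.asarray(self.positions_cM, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if np.any(np.diff(self.positions_cM) < 0):
            raise ValidationError("marker positions must be non-decreasing")
        if self.genotypes.shape != (len(self.phenotype), len(self.positions_cM)):
            raise ValidationError("genotype matrix shape mismatch")
        bad = ~np.isin(self.genotypes, (0, 1, MISSING))
        if bad.any():
            raise ValidationError("genotypes must be 0, 1 or missing")

    @property
    def n_lines(self) -> int:
        return len(self.phenotype)

    @property
    def n_markers(self) -> int:
        return len(self.positions_cM)


@dataclass
class QtlScanResult:
    """LOD profile on a cM grid with its peak and 1.5-LOD support interval."""

    grid_cM: np.ndarray
    lod: np.ndarray
    peak_position: float
    peak_lod: float
    ci_lo: float
    ci_hi: float
    threshold: float | None = None
    n_singular: int = 0  # grid points with degenerate regression, LOD forced 0

    @property
    def significant(self) -> bool | None:
        if self.threshold is None:
            return None
        return bool(self.peak_lod >= self.threshold)


def kosambi_to_cM(r: float) -> float:
    """Kosambi map distance (cM) for a recombination fraction in [0, 0.5)."""
    if not 0.0 <= r < 0.5:
        raise ValidationError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_to_r(d_cM: float) -> float:
    """Recombination fraction implied by a Kosambi distance in cM."""
    if d_cM < 0:
        raise ValidationError(f"negative distance {d_cM}")
    e = math.exp(4.0 * d_cM / 100.0)
    return (e - 1.0) / (2.0 * (e + 1.0))


def genotype_probability(
    left_genotype: int | None,
    right_genotype: int | None,
    dist_left_cM: float,
    dist_right_cM: float,
) -> float:
    """P(parent-1 allele) at a query position between two typed markers.

    For a DH line the allele at the query either matches or mismatches each
    flanking marker with the Kosambi-implied recombination probability; the
    two flanks combine by enumerating the query's two possible states.
    ``None`` flanks (chromosome end or untyped) drop out of the product.
    """
    if left_genotype is None and right_genotype is None:
        raise InsufficientDataError("no typed marker flanks the query")
    w1 = w0 = 1.0
    if left_genotype is not None:
        r = kosambi_to_r(dist_left_cM)
        w1 *= (1.0 - r) if left_genotype == 1 else r
        w0 *= r if left_genotype == 1 else (1.0 - r)
    if right_genotype is not None:
        r = kosambi_to_r(dist_right_cM)
        w1 *= (1.0 - r) if right_genotype == 1 else r
        w0 *= r if right_genotype == 1 else (1.0 - r)
    return w1 / (w1 + w0)


def expected_genotypes(pop: DhPopulation, grid_cM: np.ndarray) -> np.ndarray:
    """n_lines x n_grid matrix of P(parent-1 allele) at each grid position.

    Lines with complete genotypes are handled vectorised per grid interval;
    lines with missing flanking markers fall back to the nearest typed
    markers on each side.
    """
    grid_cM = np.asarray(grid_cM, dtype=float)
    pos = pop.positions_cM
    G = pop.genotypes
    n, m = G.shape
    out = np.empty((n, len(grid_cM)))
    complete = ~np.any(G == MISSING, axis=1)

    for gi, q in enumerate(grid_cM):
        right = int(np.searchsorted(pos, q, side="left"))
        left = right - 1
        if right < m and pos[right] == q:
            left = right  # exactly on a marker
        li = min(left, m - 1) if left >= 0 else None
        ri = right if right < m else None
        if li is not None and ri is not None and li == ri:
            # typed marker: probability is the genotype itself
            col = G[:, li].astype(float)
            miss = G[:, li] == MISSING
        else:
            dl = q - pos[li] if li is not None else 0.0
            dr = pos[ri] - q if ri is not None else 0.0
            col = np.empty(n)
            if li is None:
                rr = kosambi_to_r(dr)
                col[:] = np.where(G[:, ri] == 1, 1.0 - rr, rr)
                miss = G[:, ri] == MISSING
            elif ri is None:
                rl = kosambi_to_r(dl)
                col[:] = np.where(G[:, li] == 1, 1.0 - rl, rl)
                miss = G[:, li] == MISSING
            else:
                rl, rr = kosambi_to_r(dl), kosambi_to_r(dr)
                gl, gr = G[:, li], G[:, ri]
                w1 = (np.where(gl == 1, 1 - rl, rl)
                      * np.where(gr == 1, 1 - rr, rr))
                w0 = (np.where(gl == 1, rl, 1 - rl)
                      * np.where(gr == 1, rr, 1 - rr))
                col = w1 / (w1 + w0)
                miss = (gl == MISSING) | (gr == MISSING)
        out[:, gi] = col
        # incomplete lines: nearest typed markers on each side of q
        for line in np.nonzero(miss & ~complete)[0]:
            typed = np.nonzero(G[line] != MISSING)[0]
            if typed.size == 0:
                raise InsufficientDataError(f"line {line} has no typed marker")
            lt = typed[pos[typed] <= q]
            rt = typed[pos[typed] > q]
            lg = int(G[line, lt[-1]]) if lt.size else None
            rg = int(G[line, rt[0]]) if rt.size else None
            out[line, gi] = genotype_probability(
                lg, rg,
                q - pos[lt[-1]] if lt.size else 0.0,
                pos[rt[0]] - q if rt.size else 0.0)
    return out


def _lod_profile(x_grid: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """LOD at each grid column of x_grid via (n/2) log10(RSS0/RSS1)."""
    n = len(y)
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    xc = x_grid - x_grid.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    singular = sxx < 1e-12
    n_singular = int(singular.sum())
    rss1 = ss_y - np.where(singular, 0.0, sxy**2 / np.where(singular, 1.0, sxx))
    rss1 = np.maximum(rss1, ss_y * 1e-15)  # perfect fits: finite, huge LOD
    lod = (n / 2.0) * np.log10(ss_y / rss1)
    lod[singular] = 0.0
    return np.maximum(lod, 0.0), n_singular


def hk_scan(pop: DhPopulation, step: float = 1.0) -> QtlScanResult:
    """Single-QTL Haley-Knott scan on a cM grid of the given step.

    The grid runs from the first to the last marker; marker positions
    themselves are included in the grid when they fall on it.  The support
    interval is the contiguous grid region around the peak with
    LOD >= peak - 1.5.
    """
    if np.var(pop.phenotype) == 0:
        raise ValidationError("phenotype has zero variance")
    lo, hi = pop.positions_cM[0], pop.positions_cM[-1]
    grid = np.arange(lo, hi + step / 2.0, step)
    if grid[-1] < hi:
        grid = np.append(grid, hi)
    x = expected_genotypes(pop, grid)
    lod, n_singular = _lod_profile(x, pop.phenotype)

    peak = int(np.argmax(lod))
    drop = lod[peak] - 1.5
    lo_i = peak
    while lo_i > 0 and lod[lo_i - 1] >= drop:
        lo_i -= 1
    hi_i = peak
    while hi_i < len(grid) - 1 and lod[hi_i + 1] >= drop:
        hi_i += 1
    return QtlScanResult(
        grid_cM=grid, lod=lod,
        peak_position=float(grid[peak]), peak_lod=float(lod[peak]),
        ci_lo=float(grid[lo_i]), ci_hi=float(grid[hi_i]),
        n_singular=n_singular)


def permutation_threshold(
    pop: DhPopulation,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step: float = 1.0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is shuffled against the genotype rows ``n_perm``
    times; the threshold is the (1-alpha) quantile of each permutation's
    maximum LOD over the scan grid.
    """
    if n_perm < 100:
        raise ValidationError("need >= 100 permutations for a stable quantile")
    if np.var(pop.phenotype) == 0:
        raise ValidationError("phenotype has zero variance")
    lo, hi = pop.positions_cM[0], pop.positions_cM[-1]
    grid = np.arange(lo, hi + step / 2.0, step)
    x = expected_genotypes(pop, grid)
    xc = x - x.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    ok = sxx > 1e-12

    rng = np.random.default_rng(seed)
    n = pop.n_lines
    perms = np.empty((n, n_perm))
    y = pop.phenotype
    for p in range(n_perm):
        perms[:, p] = y[rng.permutation(n)]
    pc = perms - perms.mean(axis=0)
    ss_y = np.einsum("ij,ij->j", pc, pc)
    cross = xc[:, ok].T @ pc                      # grid x perms
    r2 = cross**2 / (sxx[ok, None] * ss_y[None, :])
    max_lod = (-(n / 2.0) * np.log10(1.0 - r2.max(axis=0)))
    return float(np.quantile(max_lod, 1.0 - alpha))


def recombination_rate(physical_length_bp: float, map_length_cM: float) -> float:
    """Average kbp per cM: physical map length over genetic map length."""
    if map_length_cM <= 0:
        raise ValidationError("map length must be positive")
    return (physical_length_bp / 1000.0) / map_length_cM
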