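"""Candidate-gene screening in QTL intervals and indel-ecotype association.

A gene inside a QTL interval is a *candidate* if it is annotated with a GO
term related to the interval's trait (flowering and/or root, by keyword
match on term names) and *carries candidate polymorphism* if at least one
nonsynonymous SNP falls in its CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .effects import GeneModel
from .errors import ValidationError

DEFAULT_KEYWORDS: Mapping[str, str] = {
    "flower": "flowering",
    "floral": "flowering",
    "vernalization": "flowering",
    "root": "root",
}


@dataclass(frozen=True)
class QtlInterval:
    """Physical interval of a mapped QTL with the traits it affects."""

    qtl_id: str
    chromosome: str
    start: int
    end: int
    traits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"{self.qtl_id}: start must precede end")
        bad = self.traits - {"flowering", "root"}
        if bad:
            raise ValidationError(f"{self.qtl_id}: unknown traits {sorted(bad)}")


@dataclass
class CandidateRow:
    """Counts for one interval: genes, nonsynonymous carriers, per-category
    candidates (with_ns / annotated).  Categories absent from the interval's
    trait set are None (printed n/a)."""

    qtl_id: str
    total_genes: int
    genes_with_ns: int
    flowering_with_ns: int | None
    flowering_annotated: int | None
    root_with_ns: int | None
    root_annotated: int | None
    gene_lists: dict[str, list[str]] = field(default_factory=dict)


def build_keyword_map(
    term_names: Mapping[str, str],
    keywords: Mapping[str, str] = DEFAULT_KEYWORDS,
) -> dict[str, str]:
    """term-id -> category for every term whose name contains a keyword."""
    out = {}
    for term, name in term_names.items():
        lowered = name.lower()
        for kw, category in keywords.items():
            if kw in lowered:
                out[term] = category
                break
    return out


def _overlaps(model: GeneModel, interval: QtlInterval) -> bool:
    # half-open intersection; a gene partially inside counts as inside
    s, e = model.span
    return model.chromosome == interval.chromosome and s < interval.end and e > interval.start


def screen_interval(
    interval: QtlInterval,
    models: Sequence[GeneModel],
    classified: pd.DataFrame,
    keyword_map: Mapping[str, str],
) -> CandidateRow:
    """Table-4-style candidate counts for one QTL interval.

    ``classified`` is the per-call effect table (from
    :func:`parentdiff.effects.classify_calls`); a gene carries candidate
    polymorphism iff >= 1 of its CDS calls is nonsynonymous.
    """
    genes = [m for m in models if _overlaps(m, interval)]
    ns_calls = classified[classified["effect"] == "nonsynonymous"]
    ns_genes: set[str] = set()
    for ids in ns_calls["gene_ids"]:
        ns_genes.update(g for g in str(ids).split(",") if g)

    with_ns = [m for m in genes if m.gene_id in ns_genes]
    row = CandidateRow(
        qtl_id=interval.qtl_id,
        total_genes=len(genes),
        genes_with_ns=len(with_ns),
        flowering_with_ns=None, flowering_annotated=None,
        root_with_ns=None, root_annotated=None,
    )
    row.gene_lists["with_ns"] = sorted(m.gene_id for m in with_ns)
    for category in ("flowering", "root"):
        if category not in interval.traits:
            continue
        annotated = [m for m in genes
                     if any(keyword_map.get(t) == category for t in m.go_terms)]
        hits = [m for m in annotated if m.gene_id in ns_genes]
        setattr(row, f"{category}_annotated", len(annotated))
        setattr(row, f"{category}_with_ns", len(hits))
        row.gene_lists[category] = sorted(m.gene_id for m in hits)
    return row


def report_frame(rows: Iterable[CandidateRow]) -> pd.DataFrame:
    """Stack interval rows plus a Total row summing each column."""
    records = []
    for r in rows:
        records.append({
            "qtl_id": r.qtl_id, "total_genes": r.total_genes,
            "genes_with_ns": r.genes_with_ns,
            "flowering": (f"{r.flowering_with_ns} / {r.flowering_annotated}"
                          if r.flowering_annotated is not None else "n/a"),
            "root": (f"{r.root_with_ns} / {r.root_annotated}"
                     if r.root_annotated is not None else "n/a"),
        })
    return pd.DataFrame(records)


def total_row(rows: Sequence[CandidateRow]) -> CandidateRow:
    """Column sums across intervals (categories sum over reporting intervals)."""
    def _sum(attr: str) -> int | None:
        vals = [getattr(r, attr) for r in rows if getattr(r, attr) is not None]
        return sum(vals) if vals else None

    return CandidateRow(
        qtl_id="Total",
        total_genes=sum(r.total_genes for r in rows),
        genes_with_ns=sum(r.genes_with_ns for r in rows),
        flowering_with_ns=_sum("flowering_with_ns"),
        flowering_annotated=_sum("flowering_annotated"),
        root_with_ns=_sum("root_with_ns"),
        root_annotated=_sum("root_annotated"),
    )


def ecotype_association(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact P for a 2x2 insertion-by-ecotype table."""
    t = [[int(x) for x in row] for row in table]
    if len(t) != 2 or any(len(row) != 2 for row in t):
        raise ValidationError("expected a 2x2 table")
    if any(x < 0 for row in t for x in row):
        raise ValidationError("counts must be nonnegative")
    rows_ok = all(sum(row) > 0 for row in t)
    cols_ok = all(t[0][j] + t[1][j] > 0 for j in range(2))
    if not (rows_ok and cols_ok):
        raise ValidationError("empty margin in 2x2 table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)
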