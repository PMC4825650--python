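"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython, VCF reading through pysam, GFF3 reading
through gffutils.  The VCF writer is a small v4.2 text emitter (QUAL column
plus INFO keys DP, AF and PNR for the caller's probability-not-reference);
coordinates are 0-based half-open in memory and 1-based in GFF3/VCF on disk.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .effects import GeneModel
from .qtl import MISSING, DhPopulation
from .simulate import GenomeTrio, SyntheticTruth
from .variants import VariantCall


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path: str | Path, models: Sequence[GeneModel],
               source: str = "parentdiff") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            attrs = f"ID={m.gene_id}"
            if m.go_terms:
                attrs += ";Ontology_term=" + ",".join(sorted(m.go_terms))
            fh.write(f"{m.chromosome}\t{source}\tgene\t{s + 1}\t{e}\t.\t"
                     f"{m.strand}\t.\t{attrs}\n")
            fh.write(f"{m.chromosome}\t{source}\tmRNA\t{s + 1}\t{e}\t.\t"
                     f"{m.strand}\t.\tID={m.gene_id}.t1;Parent={m.gene_id}\n")
            intervals = (m.cds_intervals if m.strand == "+"
                         else m.cds_intervals[::-1])
            phase = 0
            for cs, ce in intervals:
                fh.write(f"{m.chromosome}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t"
                         f"{m.strand}\t{phase}\t"
                         f"ID=cds.{m.gene_id};Parent={m.gene_id}.t1\n")
                phase = (3 - ((ce - cs) - phase) % 3) % 3


def read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        intervals = sorted((cds.start - 1, cds.end)
                           for cds in db.children(gene, featuretype="CDS"))
        terms = frozenset(gene.attributes.get("Ontology_term", []))
        models.append(GeneModel(gene_id=gene.id, chromosome=gene.seqid,
                                strand=gene.strand, cds_intervals=intervals,
                                go_terms=terms))
    return models


_VCF_HEADER = """##fileformat=VCFv4.2
##source=parentdiff
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=PNR,Number=1,Type=Float,Description="Probability not reference">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path: str | Path, calls: Sequence[VariantCall],
              contigs: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        lines = _VCF_HEADER.splitlines(keepends=True)
        fh.writelines(lines[:-1])
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(lines[-1])
        for c in sorted(calls, key=lambda v: v.key):
            fh.write(f"{c.chromosome}\t{c.position + 1}\t.\t{c.ref_allele}\t"
                     f"{c.alt_allele}\t{c.quality:.1f}\t.\t"
                     f"DP={c.depth};AF={c.alt_frequency:.4f};"
                     f"PNR={c.prob_not_ref:.4f}\n")


def read_vcf(path: str | Path, parent: str = "") -> list[VariantCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            afs = info["AF"]
            if not isinstance(afs, tuple):
                afs = (afs,) * len(rec.alts or ())
            for alt, af in zip(rec.alts or (), afs):
                calls.append(VariantCall(
                    chromosome=rec.chrom, position=rec.pos - 1,
                    ref_allele=rec.ref, alt_allele=alt,
                    quality=float(rec.qual),
                    depth=int(info["DP"]),
                    alt_frequency=float(af),
                    prob_not_ref=float(info["PNR"]),
                    parent=parent))
    return calls


def write_bed(path: str | Path,
              intervals: Mapping[str, Sequence[tuple[int, int]]]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    for row in df.itertuples(index=False):
        out.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    return out


def write_go_table(path: str | Path, go_table: Sequence[tuple[str, str]],
                   term_names: Mapping[str, str] | None = None) -> None:
    df = pd.DataFrame(go_table, columns=["gene_id", "term_id"])
    if term_names is not None:
        df["term_name"] = df["term_id"].map(term_names)
    df.to_csv(path, sep="\t", index=False)


def read_go_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(path: str | Path, truth: SyntheticTruth) -> None:
    payload = {
        "planted_variants": [list(v) for v in truth.planted_variants],
        "planted_indel": list(truth.planted_indel),
        "enriched_term": truth.enriched_term,
        "dh_qtl": [list(q) for q in truth.dh_qtl],
        "hemi_artifacts": [list(h) for h in truth.hemi_artifacts],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> SyntheticTruth:
    raw = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_variants=[tuple(v) for v in raw["planted_variants"]],
        planted_indel=tuple(raw["planted_indel"]),
        enriched_term=raw["enriched_term"],
        dh_qtl=[tuple(q) for q in raw["dh_qtl"]],
        hemi_artifacts=[tuple(h) for h in raw["hemi_artifacts"]],
    )


def write_dh_population(prefix: str | Path, pop: DhPopulation) -> None:
    """Genotype, map and phenotype CSVs under ``<prefix>_{geno,map,pheno}.csv``."""
    prefix = str(prefix)
    geno = pd.DataFrame(pop.genotypes, columns=pop.marker_ids)
    geno.replace(MISSING, pd.NA).to_csv(f"{prefix}_geno.csv", index=False)
    pd.DataFrame({"marker": pop.marker_ids, "chromosome": pop.chromosome,
                  "position_cM": pop.positions_cM}
                 ).to_csv(f"{prefix}_map.csv", index=False)
    pd.DataFrame({"phenotype": pop.phenotype}
                 ).to_csv(f"{prefix}_pheno.csv", index=False)


def read_dh_population(prefix: str | Path) -> DhPopulation:
    prefix = str(prefix)
    geno = pd.read_csv(f"{prefix}_geno.csv")
    gmap = pd.read_csv(f"{prefix}_map.csv")
    pheno = pd.read_csv(f"{prefix}_pheno.csv")
    matrix = geno.fillna(MISSING).to_numpy(dtype=np.int8)
    return DhPopulation(marker_ids=list(gmap["marker"]),
                        positions_cM=gmap["position_cM"].to_numpy(),
                        genotypes=matrix,
                        phenotype=pheno["phenotype"].to_numpy(),
                        chromosome=str(gmap["chromosome"].iloc[0]))


def write_trio(out_dir: str | Path, trio: GenomeTrio) -> dict[str, Path]:
    """Write a full trio to a directory; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = {c: len(s) for c, s in trio.reference.items()}
    paths = {
        "reference": out / "reference.fasta",
        "genes": out / "genes.gff3",
        "parent1": out / "parent1.vcf",
        "parent2": out / "parent2.vcf",
        "callable": out / "callable.bed",
        "go": out / "go_terms.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(paths["reference"], trio.reference)
    write_gff3(paths["genes"], trio.models)
    write_vcf(paths["parent1"], trio.parent1_calls, contigs)
    write_vcf(paths["parent2"], trio.parent2_calls, contigs)
    write_bed(paths["callable"], trio.callable_intervals)
    write_go_table(paths["go"], trio.go_table, trio.term_names)
    write_truth(paths["truth"], trio.truth)
    return paths
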