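#!/usr/bin/env python
"""Filter both parents' calls, exclude hemi-SNPs, derive the three
comparison lists, and apply the manual-review accuracy correction.

Reads results/sim/ (run 01_simulate.py first); writes
results/comparison_summary.tsv and the three per-list VCFs.
"""

import argparse
from pathlib import Path

import pandas as pd

import parentdiff as pdx
import parentdiff.io as pio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    sets, hemi_counts = {}, {}
    for name in ("parent1", "parent2"):
        raw = pio.read_vcf(args.sim / f"{name}.vcf", parent=name)
        kept = pdx.filter_calls(raw)  # Q>=30, AF>=5%, DP>=5, PNR>=0.90
        clean, hemi = pdx.flag_hemi_snps(kept)
        sets[name], hemi_counts[name] = clean, len(hemi)
        print(f"{name}: {len(raw)} calls, {len(kept)} pass filters, "
              f"{len(hemi)} hemi-SNPs excluded, {len(clean)} clean")

    result = pdx.compare_parents(sets["parent1"], sets["parent2"])
    # accuracy correction from the manual review of 500 random calls
    est = pdx.estimate_accuracy(500, 414)
    raw_poly = len(result.polymorphic_between_parents)
    corrected = est.corrected_count(raw_poly)

    args.out.mkdir(parents=True, exist_ok=True)
    pio.write_vcf(args.out / "shared_vs_reference.vcf",
                  result.shared_vs_reference)
    pio.write_vcf(args.out / "parent1_only.vcf", result.parent1_only)
    pio.write_vcf(args.out / "parent2_only.vcf", result.parent2_only)
    summary = pd.DataFrame([
        ("shared_vs_reference", len(result.shared_vs_reference)),
        ("parent1_only", len(result.parent1_only)),
        ("parent2_only", len(result.parent2_only)),
        ("polymorphic_between_parents", raw_poly),
        ("hemi_excluded_parent1", hemi_counts["parent1"]),
        ("hemi_excluded_parent2", hemi_counts["parent2"]),
        ("accuracy_percent", est.percent),
        ("polymorphic_accuracy_corrected", round(corrected)),
    ], columns=["quantity", "value"])
    summary.to_csv(args.out / "comparison_summary.tsv", sep="\t", index=False)

    print(f"\nthree lists: {len(result.shared_vs_reference)} shared, "
          f"{len(result.parent1_only)} parent1-only, "
          f"{len(result.parent2_only)} parent2-only")
    print(f"manual-review accuracy {est.percent}% -> corrected polymorphic "
          f"count {raw_poly} x {est.accuracy:.3f} = {corrected:.0f}")


if __name__ == "__main__":
    main()
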