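#!/usr/bin/env python
"""Assign Y-SNP haplogroups and compare marker frequencies between populations.

Reads the haplotype table from step 01, walks each sample's 24-marker
profile down the haplogroup tree, writes the per-population haplogroup
frequency table, and runs the 2x2 chi-square comparison per testable SNP
with a Bonferroni threshold of 0.05/20.
"""

import argparse
from pathlib import Path

from ylineage.dataset import read_table, write_table
from ylineage.haplogroups import (
    assign_all,
    compare_snp_frequencies,
    haplogroup_distribution_test,
    haplogroup_frequencies,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    ds = read_table(args.outdir / "haplotypes.tsv")
    assign_all(ds)
    write_table(ds, args.outdir / "haplotypes_assigned.tsv")

    freq = haplogroup_frequencies(ds)
    freq.to_csv(args.outdir / "haplogroup_frequencies.tsv", sep="\t", index=False)
    for pop in ds.populations:
        top = (
            freq[freq.population == pop]
            .sort_values("frequency", ascending=False)
            .head(5)
        )
        pretty = ", ".join(
            f"{r.haplogroup} {100 * r.frequency:.1f}%" for r in top.itertuples()
        )
        print(f"{pop}: top lineages {pretty}")

    snp = compare_snp_frequencies(ds, correction_m=20)
    snp.to_csv(args.outdir / "snp_comparison.tsv", sep="\t", index=False)
    sig = snp[snp.significant]["snp"].tolist()
    untestable = snp[~snp.testable]["snp"].tolist()
    print(f"significant SNP frequency differences (p < 0.0025): {sig or 'none'}")
    print(f"untestable (no derived allele): {untestable or 'none'}")

    dist = haplogroup_distribution_test(ds)
    print(
        f"haplogroup distribution chi-square: X2={dist['statistic']:.2f}, "
        f"p={dist['p_value']:.3g} over {dist['n_categories']} categories"
    )


if __name__ == "__main__":
    main()
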