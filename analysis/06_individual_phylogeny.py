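#!/usr/bin/env python
"""Individual-level phylogeny: d/D distance matrices, tree, purity, NMDS.

Builds the mutation-rate-weighted Y-STR distance matrix and the Y-SNP
Hamming matrix over variant-free samples, reconstructs the
complete-linkage tree (exported as Newick), measures how well tree
clusters match haplogroup labels, and embeds both matrices with NMDS.
"""

import argparse
from pathlib import Path

from ylineage.dataset import PopulationDataset, filter_for_distance, read_table
from ylineage.distances import individual_distance_matrix
from ylineage.ordination import cluster_purity, hclust_complete, nmds, write_coordinates


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--max-samples", type=int, default=250)
    ap.add_argument("--k", type=int, default=6)
    args = ap.parse_args()

    ds = filter_for_distance(read_table(args.outdir / "haplotypes_assigned.tsv"))
    keep = list(ds)[: args.max_samples]
    ds = PopulationDataset(keep, ds.panel, ds.snp_panel)

    dm_str = individual_distance_matrix(ds, "str_d")
    dm_str.to_tsv(args.outdir / "individual_str_distances.tsv")
    dm_snp = individual_distance_matrix(ds, "snp_D")

    tree = hclust_complete(dm_str)
    (args.outdir / "individual_tree.nwk").write_text(tree.to_newick() + "\n")
    labels = {s.sample_id: s.haplogroup for s in ds}
    pur = cluster_purity(tree, labels, k=args.k)
    print(
        f"complete-linkage tree over {pur.n_leaves} samples, cut at k={args.k}: "
        f"{pur.n_misfit} misfits ({100 * pur.proportion:.1f}%)"
    )

    for name, dm in (("str", dm_str), ("snp", dm_snp)):
        emb = nmds(dm)
        write_coordinates(emb, args.outdir / f"individual_mds_{name}.tsv")
        print(
            f"individual NMDS ({name}): initial stress {emb.stress_initial:.4f}, "
            f"final {emb.stress_final:.4f}"
        )


if __name__ == "__main__":
    main()
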