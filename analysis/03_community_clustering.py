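#!/usr/bin/env python
"""Main-OTU selection and habitat clustering.

Keeps OTUs above 1 per mille relative abundance in at least one habitat
(per domain), stacks the three domains with equal weight, and clusters the
21 habitats by UPGMA on Bray-Curtis dissimilarity. The planted habitat
blocks predict that the forested-soil habitats (DH, CF) split off first.

Reads results/pooled/ and results/data/taxonomy.tsv; writes
results/community/: habitat_dendrogram.nwk, taxon_abundance_<domain>.tsv.
"""

import argparse
from pathlib import Path

import biomebridge as bb


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pooled", type=Path, default=Path("results/pooled"))
    parser.add_argument("--tax", type=Path,
                        default=Path("results/data/taxonomy.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/community"))
    parser.add_argument("--threshold", type=float, default=0.001)
    args = parser.parse_args()

    tax = bb.read_taxonomy(args.tax)
    args.out.mkdir(parents=True, exist_ok=True)
    mains = []
    for dom in ("archaea", "bacteria", "fungi"):
        pooled = bb.read_otu_table(args.pooled / f"pooled_{dom}.tsv", dom)
        main_otus = bb.main_otu_filter(pooled, threshold=args.threshold)
        print(f"{dom}: {pooled.n_otus} -> {main_otus.n_otus} main OTUs "
              f"(> {args.threshold:g} in >=1 habitat)")
        mains.append(main_otus)
        bb.write_products(bb.taxon_aggregate(main_otus, tax, "class"),
                          args.out / f"taxon_abundance_{dom}.tsv", "long_tsv")

    tree = bb.cluster_from_tables(mains, weight_domains=True)
    bb.write_products(tree, args.out / "habitat_dendrogram.nwk", "newick")
    dhcf = {h for h in tree.leaf_names if h.startswith(("DH", "CF"))}
    print("dendrogram:", tree.to_newick())
    print("forested-soil habitats form their own clade:",
          tree.is_clade(dhcf))


if __name__ == "__main__":
    main()
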