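#!/usr/bin/env python
"""Spearman co-occurrence network over the 21 pooled habitats.

Filters to OTUs above 1% relative abundance in >= 1 habitat across all
three domains, computes all pairwise Spearman correlations, keeps edges
with rho > 0.6 at one-sided P < 0.001, and reports global and per-taxon
descriptors plus recovery of the planted correlated pairs.

Reads results/pooled/ and results/data/; writes results/network/:
network.graphml, network_edges.tsv, descriptor tables.
"""

import argparse
from pathlib import Path

import pandas as pd

import biomebridge as bb


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pooled", type=Path, default=Path("results/pooled"))
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/network"))
    parser.add_argument("--threshold", type=float, default=0.01)
    parser.add_argument("--rho-min", type=float, default=0.6)
    parser.add_argument("--alpha", type=float, default=0.001)
    args = parser.parse_args()

    tax = bb.read_taxonomy(args.data / "taxonomy.tsv")
    truth = pd.read_csv(args.data / "ground_truth.tsv", sep="\t",
                        index_col="otu_id")
    args.out.mkdir(parents=True, exist_ok=True)

    tables = [bb.read_otu_table(args.pooled / f"pooled_{dom}.tsv", dom)
              for dom in ("archaea", "bacteria", "fungi")]
    merged = bb.network_candidate_filter(tables, threshold=args.threshold)
    print(f"candidates after >{args.threshold:.0%} filter: "
          f"{merged.n_otus} OTUs")
    correlations = bb.spearman_all_pairs(merged, method="t_approx")
    net = bb.edge_selection(correlations, rho_min=args.rho_min,
                            alpha=args.alpha)
    for node in net.graph.nodes:
        net.graph.nodes[node]["domain"] = tax.domain(node)
        net.graph.nodes[node]["taxon"] = tax.taxon_at(node, 1)
    bb.write_products(net, args.out / "network_edges.tsv", "edgelist")
    bb.write_products(net, args.out / "network.graphml", "graphml")
    desc = bb.network_descriptors(net, tax)
    for name in ("per_domain", "per_taxon", "taxon_pairs"):
        bb.write_products(desc[name], args.out / f"network_{name}.tsv",
                          "long_tsv")
    g = desc["global"]
    print(f"network: {g['n_nodes']} nodes, {g['n_edges']} edges, "
          f"connectivity index E/N = {g['connectivity_index']:.1f}, "
          f"mean degree 2E/N = {g['mean_degree']:.1f}, "
          f"max degree {g['max_degree']} ({', '.join(g['max_degree_otus'])})")
    print(desc["per_domain"].to_string(index=False))

    edges = {tuple(sorted(e)) for e in net.graph.edges}
    pair_rows = truth[truth.corr_pair >= 0]
    planted = {
        tuple(sorted(pair_rows.index[pair_rows.corr_pair == k]))
        for k in pair_rows.corr_pair.unique()}
    hits = sum(p in edges for p in planted)
    print(f"planted correlated pairs recovered as edges: "
          f"{hits}/{len(planted)}")


if __name__ == "__main__":
    main()
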