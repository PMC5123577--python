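#!/usr/bin/env python
"""Habitat-breadth classification: generalists, intermediates, specialists.

An OTU detected (pooled count >= 1) in >= 16 of the 21 habitats is a
generalist; in exactly one habitat, a specialist. Compares the classes
against the generator's ground truth.

Reads results/pooled/ and results/data/; writes results/breadth/:
generalists_<domain>.tsv, specialists_<domain>.tsv, classes_<domain>.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

import biomebridge as bb
from biomebridge.breadth import GENERALIST, SPECIALIST


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pooled", type=Path, default=Path("results/pooled"))
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/breadth"))
    parser.add_argument("--generalist-min", type=int, default=16)
    args = parser.parse_args()

    tax = bb.read_taxonomy(args.data / "taxonomy.tsv")
    truth = pd.read_csv(args.data / "ground_truth.tsv", sep="\t",
                        index_col="otu_id")
    args.out.mkdir(parents=True, exist_ok=True)

    gen_hits = gen_total = spec_hits = spec_total = 0
    for dom in ("bacteria", "fungi", "archaea"):
        pooled = bb.read_otu_table(args.pooled / f"pooled_{dom}.tsv", dom)
        classified = bb.classify_breadth(
            bb.occurrence_profile(pooled), n_habitats=pooled.n_samples,
            generalist_min=args.generalist_min)
        gen, spec = bb.breadth_summary(classified, pooled, tax)
        bb.write_products(gen, args.out / f"generalists_{dom}.tsv", "long_tsv")
        bb.write_products(spec, args.out / f"specialists_{dom}.tsv", "long_tsv")
        classes = pd.DataFrame(
            [(p.otu_id, p.occurrence, p.breadth_class) for p in classified],
            columns=["otu_id", "occurrence", "breadth_class"])
        bb.write_products(classes, args.out / f"classes_{dom}.tsv", "long_tsv")
        counts = classes.breadth_class.value_counts().to_dict()
        print(f"{dom}: {counts}")
        cls = dict(zip(classes.otu_id, classes.breadth_class))
        dom_truth = truth[truth.domain == dom]
        for otu in dom_truth.index[dom_truth.true_class == "generalist"]:
            gen_total += 1
            gen_hits += cls.get(otu) == GENERALIST
        for otu in dom_truth.index[dom_truth.true_class == "specialist"]:
            spec_total += 1
            spec_hits += cls.get(otu) == SPECIALIST
    print(f"planted generalists recovered: {gen_hits}/{gen_total}")
    print(f"planted specialists recovered: {spec_hits}/{spec_total}")


if __name__ == "__main__":
    main()
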