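"""End-to-end orchestration: QC -> pooling -> main-OTU filter -> clustering
-> habitat-breadth classification -> co-occurrence network, from a single
config, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import core_io
from .breadth import breadth_summary, classify_breadth, occurrence_profile
from .community import (cluster_habitats, joint_profile, main_otu_filter,
                        taxon_aggregate)
from .core_io import (OtuTable, read_otu_table, read_sample_metadata,
                      read_taxonomy, write_edge_list, write_graphml,
                      write_long_table, write_newick, write_otu_table)
from .network import (edge_selection, network_candidate_filter,
                      network_descriptors, spearman_all_pairs)
from .replicate_qc import bray_curtis, pool_replicates, relative_abundance, \
    replicate_distance_test
from .synthetic import SyntheticSpec, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the analysis; defaults reproduce the published
    procedure (1 per mille main-OTU filter, 1% network filter, rho > 0.6 at
    one-sided P < 0.001, generalists at >= 16 of 21 habitats)."""

    out_dir: str = "results/run"
    otu_tables: dict[str, str] | None = None   # domain -> path; fungi may be a list
    metadata: str | None = None
    taxonomy: str | None = None
    synthetic: SyntheticSpec | None = None
    main_otu_threshold: float = 0.001
    network_threshold: float = 0.01
    rho_min: float = 0.6
    alpha: float = 0.001
    generalist_min: int = 16
    qc_alpha: float = 0.001
    min_count: int = 1
    weight_domains: bool = True
    include_isolated: bool = False
    two_sided: bool = False
    bh_correct: bool = False
    force: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.otu_tables is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError(
                "exactly one of otu_tables/metadata/taxonomy or a synthetic "
                "spec must be configured")
        if has_files and (self.metadata is None or self.taxonomy is None):
            raise ValueError("file inputs require metadata and taxonomy paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        # out_dir is a destination, not part of the scientific config:
        # excluding it keeps manifests byte-identical across destinations
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        dataset = simulate_dataset(spec)
        return dataset.tables, dataset.metadata, dataset.taxonomy
    tables = {}
    for dom, path in config.otu_tables.items():
        if isinstance(path, (list, tuple)):
            # e.g. two fungal marker tables: union of their OTU sets
            log.info("%s: union of %d tables %s", dom, len(path), list(path))
            parts = [read_otu_table(p, dom) for p in path]
            import pandas as pd
            merged = pd.concat([p.counts for p in parts], axis=0)
            if merged.index.has_duplicates:
                raise core_io.UniquenessError(
                    f"{dom}: OTU ids overlap across unioned tables")
            tables[dom] = OtuTable(counts=merged, domain_label=dom)
        else:
            tables[dom] = read_otu_table(path, dom)
    meta = read_sample_metadata(config.metadata)
    tax = read_taxonomy(config.taxonomy)
    return tables, meta, tax


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all products plus a manifest.

    Identical config + seed yields byte-identical outputs. A failed
    replicate QC halts the run unless ``force`` is set.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables, meta, tax = _load_inputs(config)
    manifest: dict = {
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # --- replicate QC, per domain ------------------------------------
    qc = {}
    for dom, table in tables.items():
        dm = bray_curtis(relative_abundance(table))
        result = replicate_distance_test(dm, meta, alpha=config.qc_alpha)
        qc[dom] = {
            "mean_within": result.mean_within,
            "mean_between": result.mean_between,
            "t_statistic": result.t_statistic,
            "p_value": result.p_value,
            "passed": result.passed,
        }
        log.info("QC %s: within %.3f between %.3f p %.3g passed %s", dom,
                 result.mean_within, result.mean_between, result.p_value,
                 result.passed)
    manifest["stages"]["replicate_qc"] = qc
    if not all(v["passed"] for v in qc.values()):
        failed = [d for d, v in qc.items() if not v["passed"]]
        if not config.force:
            raise RuntimeError(
                f"replicate QC failed for {failed}; rerun with force to pool anyway")
        log.warning("replicate QC failed for %s; continuing (force)", failed)

    # --- pooling ------------------------------------------------------
    pooled = {dom: pool_replicates(t, meta) for dom, t in tables.items()}
    for dom, t in pooled.items():
        write_otu_table(t, out / f"pooled_{dom}.tsv")
    manifest["stages"]["pooling"] = {
        dom: {"samples_in": tables[dom].n_samples, "habitats": t.n_samples,
              "otus": t.n_otus}
        for dom, t in pooled.items()
    }

    # --- main-OTU filter + clustering --------------------------------
    main = {dom: main_otu_filter(t, config.main_otu_threshold)
            for dom, t in pooled.items()}
    manifest["stages"]["main_otu_filter"] = {
        dom: {"otus_in": pooled[dom].n_otus, "otus_kept": t.n_otus}
        for dom, t in main.items()
    }
    domain_order = sorted(main)
    profile = joint_profile([main[d] for d in domain_order],
                            weight_domains=config.weight_domains)
    dm = bray_curtis(profile)
    tree = cluster_habitats(dm)
    write_newick(tree, out / "habitat_dendrogram.nwk")
    for dom in domain_order:
        write_long_table(taxon_aggregate(main[dom], tax, "class"),
                         out / f"taxon_abundance_{dom}.tsv")

    # --- habitat breadth ---------------------------------------------
    breadth_counts = {}
    gen_frames, spec_frames = [], []
    n_habitats = pooled[domain_order[0]].n_samples
    for dom in domain_order:
        profiles = occurrence_profile(pooled[dom], min_count=config.min_count)
        classified = classify_breadth(profiles, n_habitats=n_habitats,
                                      generalist_min=config.generalist_min)
        gen, spec = breadth_summary(classified, pooled[dom], tax)
        gen_frames.append(gen)
        spec_frames.append(spec)
        from collections import Counter
        breadth_counts[dom] = dict(Counter(
            p.breadth_class for p in classified))
    import pandas as pd
    write_long_table(pd.concat(gen_frames, ignore_index=True),
                     out / "generalists.tsv")
    write_long_table(pd.concat(spec_frames, ignore_index=True),
                     out / "specialists.tsv")
    manifest["stages"]["habitat_breadth"] = breadth_counts

    # --- co-occurrence network ---------------------------------------
    merged = network_candidate_filter([main[d] for d in domain_order],
                                      threshold=config.network_threshold)
    correlations = spearman_all_pairs(merged, method="t_approx",
                                      two_sided=config.two_sided,
                                      seed=config.seed)
    net = edge_selection(correlations, rho_min=config.rho_min,
                         alpha=config.alpha,
                         include_isolated=config.include_isolated,
                         all_otus=merged.otu_ids,
                         bh_correct=config.bh_correct)
    write_edge_list(net, out / "network_edges.tsv")
    for node in net.graph.nodes:
        net.graph.nodes[node]["domain"] = tax.domain(node)
        net.graph.nodes[node]["taxon"] = tax.taxon_at(node, 1)
    write_graphml(net, out / "network.graphml")
    desc = network_descriptors(net, tax)
    write_long_table(desc["per_domain"], out / "network_per_domain.tsv")
    write_long_table(desc["per_taxon"], out / "network_per_taxon.tsv")
    write_long_table(desc["taxon_pairs"], out / "network_taxon_pairs.tsv")
    manifest["stages"]["network"] = {
        "candidates": merged.n_otus,
        "pairs_tested": len(correlations),
        **{k: v for k, v in desc["global"].items()},
    }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str) + "\n")
    return manifest
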