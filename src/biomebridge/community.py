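"""Community structure over pooled habitats: main-OTU selection, UPGMA
clustering on Bray-Curtis dissimilarity, and taxon-level abundance tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import OtuTable, TaxonomyMap
from .replicate_qc import DistanceMatrix, bray_curtis, relative_abundance

#: named rank levels into the taxonomy rank path
RANK_LEVELS = {"phylum": 0, "class": 1}


def main_otu_filter(table: OtuTable, threshold: float = 0.001) -> OtuTable:
    """Keep OTUs whose relative abundance exceeds ``threshold`` (default 1
    per mille) in at least one habitat; applied per domain table.

    The inequality is strict ("higher than"), so an OTU sitting exactly at
    the threshold everywhere is removed.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    rel = relative_abundance(table)
    keep = (rel > threshold).any(axis=1)
    return OtuTable(counts=table.counts.loc[keep],
                    domain_label=table.domain_label)


# ---------------------------------------------------------------------------
# UPGMA clustering

@dataclass
class TreeNode:
    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()
    leaves: tuple[str, ...] = field(default_factory=tuple)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Binary UPGMA merge tree over habitat leaves.

    Merge heights are on the Bray-Curtis scale; branch lengths in the Newick
    export follow the ultrametric half-height convention (leaf-to-root path
    length equals half the root merge height).
    """

    root: TreeNode
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return self.root.leaves

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            length = parent_height / 2 - node.height / 2
            if node.is_leaf():
                return f"{node.name}:{length:g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length:g}"

        if self.root.is_leaf():
            return f"{self.root.name};"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise merge heights (the standard cophenetic distance)."""
        ids = sorted(self.leaf_names)
        idx = {name: i for i, name in enumerate(ids)}
        values = np.zeros((len(ids), len(ids)))
        for group_a, group_b, height in self.merges:
            for a in group_a:
                for b in group_b:
                    values[idx[a], idx[b]] = height
                    values[idx[b], idx[a]] = height
        return DistanceMatrix(ids=ids, values=values)

    def is_clade(self, names: set[str]) -> bool:
        """True if ``names`` is exactly the leaf set of some subtree."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            if set(node.leaves) == names:
                return True
            stack.extend(node.children)
        return False


def upgma(dm: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering (average linkage by default, i.e. UPGMA;
    single and complete available) with deterministic tie-breaking: among
    equally distant pairs, the lexicographically smallest (by sorted leaf
    tuples) is merged first."""
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains NaN")
    nodes: dict[tuple[str, ...], TreeNode] = {
        (name,): TreeNode(height=0.0, name=name, leaves=(name,))
        for name in dm.ids
    }
    sizes = {key: 1 for key in nodes}
    dist: dict[frozenset, float] = {}
    keys = sorted(nodes)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            dist[frozenset((a, b))] = dm.between(a[0], b[0])
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    while len(nodes) > 1:
        best = min(
            ((d, tuple(sorted(pair))) for pair, d in dist.items()),
            key=lambda item: (item[0], item[1]),
        )
        height, (a, b) = best[0], best[1]
        node_a, node_b = nodes.pop(a), nodes.pop(b)
        merged_key = tuple(sorted(a + b))
        children = tuple(sorted((node_a, node_b),
                                key=lambda n: n.leaves))
        new_node = TreeNode(height=height, children=children,
                            leaves=merged_key)
        merges.append((a, b, height))
        na, nb = sizes.pop(a), sizes.pop(b)
        del dist[frozenset((a, b))]
        for other in list(nodes):
            d_a = dist.pop(frozenset((a, other)))
            d_b = dist.pop(frozenset((b, other)))
            if linkage == "average":
                d_new = (na * d_a + nb * d_b) / (na + nb)
            elif linkage == "single":
                d_new = min(d_a, d_b)
            else:
                d_new = max(d_a, d_b)
            dist[frozenset((merged_key, other))] = d_new
        nodes[merged_key] = new_node
        sizes[merged_key] = na + nb

    return Dendrogram(root=next(iter(nodes.values())), merges=merges)


def joint_profile(tables: list[OtuTable], weight_domains: bool = True) -> pd.DataFrame:
    """Stack per-domain relative-abundance profiles over shared habitats.

    With ``weight_domains`` each domain block is renormalized to equal
    weight (columns of each block sum to 1, then divided by the number of
    domains) so the domain with the most OTUs does not dominate the
    dissimilarity; disable to concatenate raw relative abundances.
    """
    columns = list(tables[0].counts.columns)
    for t in tables[1:]:
        if list(t.counts.columns) != columns:
            raise ValueError("habitat columns differ across domain tables")
    blocks = []
    for t in tables:
        rel = relative_abundance(t)
        if weight_domains:
            rel = rel / len(tables)
        blocks.append(rel)
    stacked = pd.concat(blocks, axis=0)
    if stacked.index.has_duplicates:
        raise ValueError("OTU ids overlap across domain tables")
    return stacked


def cluster_habitats(dm: DistanceMatrix,
                     linkage: str = "average") -> Dendrogram:
    """UPGMA dendrogram of pooled habitats from their Bray-Curtis matrix."""
    if len(dm.ids) < 2:
        raise ValueError("need at least two habitats to cluster")
    return upgma(dm, linkage=linkage)


def cluster_from_tables(tables: list[OtuTable], weight_domains: bool = True,
                        linkage: str = "average") -> Dendrogram:
    """Convenience: joint profile -> Bray-Curtis -> UPGMA."""
    return cluster_habitats(bray_curtis(joint_profile(tables, weight_domains)),
                            linkage=linkage)


def taxon_aggregate(table: OtuTable, tax: TaxonomyMap, rank: str) -> pd.DataFrame:
    """Sum relative abundances within each taxon at ``rank`` per habitat.

    Returns a long table (taxon, habitat_id, relative_abundance). OTUs with
    an unresolved rank are grouped under ``unclassified <domain>``. Per
    habitat totals equal 1 when aggregating an unfiltered table.
    """
    if rank not in RANK_LEVELS:
        raise ValueError(f"unknown rank {rank!r}; choose from {sorted(RANK_LEVELS)}")
    level = RANK_LEVELS[rank]
    missing = [o for o in table.otu_ids if o not in tax]
    if missing:
        raise KeyError(f"OTUs missing from taxonomy: {missing[:5]}")
    rel = relative_abundance(table)
    taxa = [tax.taxon_at(o, level) for o in table.otu_ids]
    agg = rel.groupby(pd.Index(taxa, name="taxon")).sum()
    long = (agg.stack().rename("relative_abundance")
            .reset_index().rename(columns={"level_1": "habitat_id"}))
    long.columns = ["taxon", "habitat_id", "relative_abundance"]
    return long.sort_values(["taxon", "habitat_id"]).reset_index(drop=True)
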