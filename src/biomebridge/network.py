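"""Spearman co-occurrence network over pooled habitats.

Abundant OTUs (>1% relative abundance in at least one habitat) from all
three domains are merged, all pairwise Spearman rank correlations of their
habitat profiles are computed, and pairs with rho > 0.6 at one-sided
P < 0.001 become edges of an undirected network. Descriptors report both
degree conventions: mean degree 2E/N and the connectivity index E/N.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import OtuTable, TaxonomyMap, UniquenessError
from .replicate_qc import relative_abundance

log = logging.getLogger(__name__)


def network_candidate_filter(tables: list[OtuTable],
                             threshold: float = 0.01) -> OtuTable:
    """Keep OTUs above ``threshold`` relative abundance in >=1 habitat and
    merge the domain tables over their shared habitat columns.

    OTU id spaces must be disjoint (ids are domain-prefixed upstream).
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    habitats = list(tables[0].counts.columns)
    for t in tables[1:]:
        if list(t.counts.columns) != habitats:
            raise ValueError("habitat sets differ across domain tables")
    survivors = []
    for t in tables:
        rel = relative_abundance(t)
        keep = (rel > threshold).any(axis=1)
        survivors.append(t.counts.loc[keep])
    merged = pd.concat(survivors, axis=0)
    if merged.index.has_duplicates:
        raise UniquenessError("OTU ids overlap across domain tables")
    return OtuTable(counts=merged, domain_label="merged")


@dataclass
class CorrelationResult:
    """One OTU pair's Spearman correlation: the edge candidate."""

    otu_a: str
    otu_b: str
    rho: float
    p_value: float
    n: int


def _spearman_rho_matrix(profiles: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(profiles, axis=1)
    return np.corrcoef(ranks)


def _t_sf(rho: np.ndarray, n: int, two_sided: bool) -> np.ndarray:
    """Upper-tail p for positive association via the t approximation (n-2 df)."""
    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    if two_sided:
        return 2 * stats.t.sf(np.abs(t), df=n - 2)
    return stats.t.sf(t, df=n - 2)


def _perm_rhos(x_ranks: np.ndarray, perms: np.ndarray) -> np.ndarray:
    xc = x_ranks - x_ranks.mean()
    denom_x = float(np.sqrt((xc * xc).sum()))
    yc = perms - perms.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((yc * yc).sum(axis=1))
    return (yc @ xc) / (denom_x * denom_y)


def _exact_perm_p(x_ranks: np.ndarray, y_ranks: np.ndarray,
                  rho_obs: float, two_sided: bool) -> float:
    """One-sided (or two-sided) p by enumerating all n! rank permutations."""
    perms = np.array(list(itertools.permutations(y_ranks)), dtype=float)
    rhos = _perm_rhos(x_ranks, perms)
    if two_sided:
        hits = np.abs(rhos) >= abs(rho_obs) - 1e-12
    else:
        hits = rhos >= rho_obs - 1e-12
    return float(hits.sum()) / math.factorial(len(x_ranks))


def _mc_perm_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float,
               two_sided: bool, n_perm: int, rng: np.random.Generator) -> float:
    perms = rng.permuted(np.tile(y_ranks, (n_perm, 1)), axis=1)
    rhos = _perm_rhos(x_ranks, perms)
    if two_sided:
        hits = np.abs(rhos) >= abs(rho_obs) - 1e-12
    else:
        hits = rhos >= rho_obs - 1e-12
    return (float(hits.sum()) + 1) / (n_perm + 1)


def spearman_all_pairs(table: OtuTable, method: str = "t_approx",
                       two_sided: bool = False, n_perm: int = 10000,
                       seed: int = 0) -> list[CorrelationResult]:
    """All pairwise Spearman correlations of OTU profiles across habitats.

    rho is the tie-corrected (Pearson-on-midranks) coefficient and does not
    depend on ``method``; the p-value is one-sided for positive association
    by default. ``t_approx`` uses the t statistic with n-2 df;
    ``exact_perm`` enumerates all n! rank permutations for n <= 8 and falls
    back to Monte Carlo permutation beyond. Constant profiles (zero rank
    variance) are skipped with a log entry.
    """
    if method not in ("t_approx", "exact_perm"):
        raise ValueError(f"unknown method {method!r}")
    rel = relative_abundance(table)
    n = rel.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 habitat observations, got {n}")
    values = rel.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    skipped = [o for o, v in zip(table.otu_ids, variable) if not v]
    if skipped:
        log.info("skipping %d constant profile(s): %s...", len(skipped),
                 skipped[:3])
    ids = [o for o, v in zip(table.otu_ids, variable) if v]
    sub = values[variable]
    ranks = stats.rankdata(sub, axis=1)
    rho_matrix = np.corrcoef(ranks)
    rng = np.random.default_rng(seed)
    results: list[CorrelationResult] = []
    if method == "t_approx":
        p_matrix = _t_sf(rho_matrix, n, two_sided)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                results.append(CorrelationResult(
                    ids[i], ids[j], float(rho_matrix[i, j]),
                    float(p_matrix[i, j]), n))
    else:
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rho = float(rho_matrix[i, j])
                if n <= 8:
                    p = _exact_perm_p(ranks[i], ranks[j], rho, two_sided)
                else:
                    p = _mc_perm_p(ranks[i], ranks[j], rho, two_sided,
                                   n_perm, rng)
                results.append(CorrelationResult(ids[i], ids[j], rho, p, n))
    return results


@dataclass
class CoNetwork:
    """Undirected co-occurrence network; edges carry rho weights."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree)

    @property
    def mean_degree(self) -> float:
        """Standard convention 2E/N."""
        return 2 * self.n_edges / self.n_nodes if self.n_nodes else 0.0

    @property
    def connectivity_index(self) -> float:
        """Edges per node, E/N. Some published network summaries report
        this quantity as the network's average connectivity; it is half the
        true mean degree and the two must not be conflated."""
        return self.n_edges / self.n_nodes if self.n_nodes else 0.0


def edge_selection(correlations: list[CorrelationResult],
                   rho_min: float = 0.6, alpha: float = 0.001,
                   include_isolated: bool = False,
                   all_otus: list[str] | None = None,
                   bh_correct: bool = False) -> CoNetwork:
    """Keep edges with rho > rho_min and p < alpha.

    The rule is the literal positive-threshold form, so strong negative
    associations are excluded. Nodes default to OTUs incident to at least
    one kept edge; with ``include_isolated`` every OTU in ``all_otus`` is a
    node. ``bh_correct`` applies Benjamini-Hochberg to the p-values first
    (the default pipeline applies no multiple-testing correction).
    """
    if not -1 <= rho_min <= 1:
        raise ValueError(f"rho_min must lie in [-1, 1], got {rho_min}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    pvals = np.array([c.p_value for c in correlations])
    if bh_correct and len(pvals):
        log.warning("applying Benjamini-Hochberg correction to %d p-values",
                    len(pvals))
        pvals = stats.false_discovery_control(pvals, method="bh")
    else:
        log.info("no multiple-testing correction applied to %d p-values",
                 len(pvals))
    graph = nx.Graph()
    if include_isolated:
        if all_otus is None:
            raise ValueError("include_isolated requires all_otus")
        graph.add_nodes_from(all_otus)
    for c, p in zip(correlations, pvals):
        if c.rho > rho_min and p < alpha:
            graph.add_edge(c.otu_a, c.otu_b, rho=c.rho, p=float(p))
    return CoNetwork(graph=graph)


def network_descriptors(net: CoNetwork, tax: TaxonomyMap) -> dict:
    """Global, per-domain, per-taxon and taxon-pair network statistics.

    Taxon labels are taken at the class/order level of the lineage. For
    taxon pairs both the edge count and the maximum endpoint-degree sum are
    reported; the two summaries are distinct and not interchangeable.
    """
    degrees = net.degrees
    nodes = list(net.graph.nodes)
    for n in nodes:
        if n not in tax:
            raise KeyError(f"network node {n!r} missing from taxonomy")
    global_stats = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "connectivity_index": net.connectivity_index,
        "mean_degree": net.mean_degree,
        "max_degree": max(degrees.values()) if degrees else 0,
        "max_degree_otus": sorted(
            [n for n, d in degrees.items()
             if degrees and d == max(degrees.values())]) if degrees else [],
    }

    def summarize(group_of) -> pd.DataFrame:
        rows: dict[str, list[int]] = {}
        for n in nodes:
            rows.setdefault(group_of(n), []).append(degrees[n])
        frame = pd.DataFrame(
            [(g, len(ds), float(np.mean(ds))) for g, ds in sorted(rows.items())],
            columns=["group", "n_nodes", "mean_degree"])
        return frame

    per_domain = summarize(tax.domain)
    per_taxon = summarize(lambda n: tax.taxon_at(n, 1))

    pair_rows: dict[tuple[str, str], dict] = {}
    for a, b in net.graph.edges:
        key = tuple(sorted((tax.taxon_at(a, 1), tax.taxon_at(b, 1))))
        entry = pair_rows.setdefault(
            key, {"edge_count": 0, "max_endpoint_degree_sum": 0})
        entry["edge_count"] += 1
        entry["max_endpoint_degree_sum"] = max(
            entry["max_endpoint_degree_sum"], degrees[a] + degrees[b])
    taxon_pairs = pd.DataFrame(
        [(a, b, v["edge_count"], v["max_endpoint_degree_sum"])
         for (a, b), v in sorted(pair_rows.items())],
        columns=["taxon_a", "taxon_b", "edge_count", "max_endpoint_degree_sum"])

    return {
        "global": global_stats,
        "per_domain": per_domain,
        "per_taxon": per_taxon,
        "taxon_pairs": taxon_pairs,
    }


def connectivity_index(n_edges: int, n_nodes: int) -> float:
    """Edges per node (the study's 'average degree' convention)."""
    return n_edges / n_nodes if n_nodes else 0.0
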