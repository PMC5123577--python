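"""Abundance filtering, Spearman correlations and network construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import biomebridge as bb
from biomebridge.core_io import UniquenessError
from biomebridge.network import CorrelationResult

from .conftest import make_table


def merged_from(rows, otus, habitats=None):
    habitats = habitats or [f"H{i}" for i in range(len(rows[0]))]
    return bb.OtuTable(
        counts=pd.DataFrame(rows, index=otus, columns=habitats),
        domain_label="merged")


class TestCandidateFilter:
    def test_kept_above_one_percent(self):
        bac = make_table([[20, 0], [980, 1000]], otus=["bac_a", "bac_b"],
                         samples=["H1", "H2"])
        merged = bb.network_candidate_filter([bac], threshold=0.01)
        assert "bac_a" in merged.otu_ids

    def test_removed_below_one_percent_everywhere(self):
        bac = make_table([[9, 9], [991, 991]], otus=["bac_a", "bac_b"],
                         samples=["H1", "H2"])
        merged = bb.network_candidate_filter([bac], threshold=0.01)
        assert "bac_a" not in merged.otu_ids

    def test_merged_count_is_sum_of_survivors(self, pooled):
        tables = [pooled[d] for d in sorted(pooled)]
        survivors = [
            int((bb.relative_abundance(t) > 0.01).any(axis=1).sum())
            for t in tables]
        merged = bb.network_candidate_filter(tables, threshold=0.01)
        assert merged.n_otus == sum(survivors)

    def test_habitat_mismatch_rejected(self):
        a = make_table([[1]], otus=["bac_a"], samples=["H1"])
        b = make_table([[1]], otus=["fun_a"], samples=["H2"], domain="fungi")
        with pytest.raises(ValueError):
            bb.network_candidate_filter([a, b])

    def test_overlapping_ids_rejected(self):
        a = make_table([[100]], otus=["x"], samples=["H1"])
        b = make_table([[100]], otus=["x"], samples=["H1"], domain="fungi")
        with pytest.raises(UniquenessError):
            bb.network_candidate_filter([a, b])


class TestSpearmanAllPairs:
    def test_perfect_monotone(self):
        t = merged_from([[1, 2, 3, 4], [2, 4, 6, 8], [10, 9, 3, 1]],
                        ["a", "b", "c"])
        res = {tuple(sorted((r.otu_a, r.otu_b))): r
               for r in bb.spearman_all_pairs(t)}
        assert res[("a", "b")].rho == pytest.approx(1.0)
        assert res[("a", "c")].rho == pytest.approx(-1.0)

    def test_exact_enumeration_hand_case(self):
        """x=(1,2,3,4), y=(1,3,2,4): rho=0.8, one-sided exact p=4/24.

        A filler OTU keeps every column total at 100 so the per-sample
        normalization preserves the ranks of x and y."""
        t = merged_from([[1, 2, 3, 4], [1, 3, 2, 4], [98, 95, 95, 92]],
                        ["a", "b", "filler"])
        res = {tuple(sorted((r.otu_a, r.otu_b))): r
               for r in bb.spearman_all_pairs(t, method="exact_perm")}
        pair = res[("a", "b")]
        assert pair.rho == pytest.approx(0.8)
        assert pair.p_value == pytest.approx(4 / 24)

    def test_rho_independent_of_method(self):
        rng = np.random.default_rng(2)
        t = merged_from(rng.integers(1, 100, (5, 8)).tolist(),
                        [f"o{i}" for i in range(5)])
        ta = bb.spearman_all_pairs(t, method="t_approx")
        ex = bb.spearman_all_pairs(t, method="exact_perm")
        for a, b in zip(ta, ex):
            assert abs(a.rho - b.rho) < 1e-12

    def test_matches_scipy_spearman(self):
        rng = np.random.default_rng(3)
        t = merged_from(rng.integers(1, 100, (4, 12)).tolist(),
                        [f"o{i}" for i in range(4)])
        rel = bb.relative_abundance(t)
        for res in bb.spearman_all_pairs(t, two_sided=True):
            rho, p = spearmanr(rel.loc[res.otu_a], rel.loc[res.otu_b])
            assert res.rho == pytest.approx(rho, abs=1e-12)
            assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_one_sided_is_half_two_sided_for_positive_rho(self):
        rng = np.random.default_rng(5)
        t = merged_from(rng.integers(1, 100, (4, 10)).tolist(),
                        [f"o{i}" for i in range(4)])
        one = bb.spearman_all_pairs(t, two_sided=False)
        two = bb.spearman_all_pairs(t, two_sided=True)
        for a, b in zip(one, two):
            if a.rho > 0:
                assert a.p_value == pytest.approx(b.p_value / 2, rel=1e-9)

    def test_constant_profile_skipped(self):
        t = merged_from([[5, 5, 5, 5], [1, 2, 3, 4], [4, 3, 2, 1]],
                        ["flat", "up", "down"])
        res = bb.spearman_all_pairs(t)
        ids = {r.otu_a for r in res} | {r.otu_b for r in res}
        assert "flat" not in ids and len(res) == 1

    def test_too_few_habitats_rejected(self):
        t = merged_from([[1, 2, 3], [3, 2, 1]], ["a", "b"])
        with pytest.raises(ValueError):
            bb.spearman_all_pairs(t)


def corr(a, b, rho, p, n=21):
    return CorrelationResult(a, b, rho, p, n)


class TestEdgeSelection:
    def test_threshold_semantics(self):
        net = bb.edge_selection([
            corr("a", "b", 0.7, 1e-4),    # kept
            corr("a", "c", 0.7, 0.01),    # fails p
            corr("b", "c", -0.9, 1e-5),   # negative: excluded literally
            corr("a", "d", 0.55, 1e-6),   # fails rho
        ])
        assert set(net.graph.edges) == {("a", "b")}

    @pytest.mark.parametrize("kwargs", [
        dict(rho_min=1.5), dict(rho_min=-2), dict(alpha=0.0), dict(alpha=1.0)])
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ValueError):
            bb.edge_selection([], **kwargs)

    def test_isolated_nodes_flag(self):
        cs = [corr("a", "b", 0.9, 1e-6), corr("a", "c", 0.1, 0.5)]
        default = bb.edge_selection(cs)
        assert set(default.graph.nodes) == {"a", "b"}
        full = bb.edge_selection(cs, include_isolated=True,
                                 all_otus=["a", "b", "c", "d"])
        assert set(full.graph.nodes) == {"a", "b", "c", "d"}

    def test_degree_sum_is_twice_edges(self, pooled):
        tables = [pooled[d] for d in sorted(pooled)]
        merged = bb.network_candidate_filter(tables)
        net = bb.edge_selection(bb.spearman_all_pairs(merged))
        assert sum(net.degrees.values()) == 2 * net.n_edges

    def test_lowering_rho_min_gives_superset(self, pooled):
        tables = [pooled[d] for d in sorted(pooled)]
        cs = bb.spearman_all_pairs(bb.network_candidate_filter(tables))
        strict = set(map(tuple, map(sorted,
                                    bb.edge_selection(cs, rho_min=0.6).graph.edges)))
        loose = set(map(tuple, map(sorted,
                                   bb.edge_selection(cs, rho_min=-1.0).graph.edges)))
        assert strict <= loose

    def test_bh_correction_never_adds_edges(self):
        cs = [corr("a", "b", 0.8, 8e-4), corr("c", "d", 0.9, 1e-6),
              corr("e", "f", 0.7, 9e-4)]
        plain = bb.edge_selection(cs)
        bh = bb.edge_selection(cs, bh_correct=True)
        assert set(bh.graph.edges) <= set(plain.graph.edges)


class TestDescriptors:
    def tax_for(self, mapping):
        return bb.TaxonomyMap(lineages={
            o: ("bacteria", ("P", t)) for o, t in mapping.items()})

    def test_triangle_degree_conventions(self):
        import networkx as nx
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")],
                         rho=0.9, p=1e-9)
        net = bb.CoNetwork(graph=g)
        assert net.mean_degree == pytest.approx(2.0)
        assert net.connectivity_index == pytest.approx(1.0)

    def test_taxon_pair_edge_counts_on_path(self):
        import networkx as nx
        g = nx.Graph()
        g.add_edge("a", "b", rho=0.9, p=1e-9)
        g.add_edge("b", "c", rho=0.8, p=1e-8)
        net = bb.CoNetwork(graph=g)
        desc = bb.network_descriptors(
            net, self.tax_for({"a": "T1", "b": "T1", "c": "T2"}))
        pairs = desc["taxon_pairs"].set_index(["taxon_a", "taxon_b"])
        assert pairs.at[("T1", "T1"), "edge_count"] == 1
        assert pairs.at[("T1", "T2"), "edge_count"] == 1

    def test_empty_network_all_zero(self):
        import networkx as nx
        desc = bb.network_descriptors(bb.CoNetwork(graph=nx.Graph()),
                                      self.tax_for({}))
        assert desc["global"]["n_nodes"] == 0
        assert desc["global"]["n_edges"] == 0
        assert desc["global"]["connectivity_index"] == 0.0

    def test_connectivity_index_helper(self):
        assert bb.connectivity_index(3, 3) == pytest.approx(1.0)
        assert bb.connectivity_index(0, 0) == 0.0
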