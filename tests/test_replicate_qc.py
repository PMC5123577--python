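"""Bray-Curtis, the replicate-similarity t-test, and pooling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import biomebridge as bb
from biomebridge.replicate_qc import DistanceMatrix

from .conftest import make_table


def bray_curtis_oracle(x, y):
    """Naive double-loop evaluation of sum|x-y| / sum(x+y)."""
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


class TestRelativeAbundance:
    def test_proportions(self):
        table = make_table([[2], [3], [5]])
        rel = bb.relative_abundance(table)
        assert list(rel["S1"]) == [0.2, 0.3, 0.5]

    def test_zero_column_rejected(self):
        table = make_table([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="S2"):
            bb.relative_abundance(table)

    @given(arrays(np.int64, (20, 8), elements=st.integers(0, 1000)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_columns_sum_to_one(self, counts):
        counts[0] += 1  # no all-zero column
        rel = bb.relative_abundance(pd.DataFrame(counts))
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)


class TestBrayCurtis:
    def test_identical_profiles_distance_zero(self):
        rel = bb.relative_abundance(make_table([[1, 1], [2, 2]]))
        assert bb.bray_curtis(rel).between("S1", "S2") == 0.0

    def test_disjoint_profiles_distance_one(self):
        rel = bb.relative_abundance(make_table([[1, 0], [0, 1]]))
        assert bb.bray_curtis(rel).between("S1", "S2") == pytest.approx(1.0)

    def test_hand_computed_value(self):
        profiles = pd.DataFrame({"x": [2, 1, 0], "y": [1, 1, 1]})
        assert bb.bray_curtis(profiles).between("x", "y") == pytest.approx(1 / 3)

    def test_all_zero_profile_rejected(self):
        profiles = pd.DataFrame({"x": [1, 1], "y": [0, 0]})
        with pytest.raises(ValueError):
            bb.bray_curtis(profiles)

    @given(arrays(np.int64, (20, 10), elements=st.integers(0, 500)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_agrees_with_double_loop_oracle(self, counts):
        counts[0] += 1
        profiles = pd.DataFrame(counts).astype(float)
        dm = bb.bray_curtis(profiles)
        for i in range(0, 10, 3):
            for j in range(i + 1, 10, 3):
                expected = bray_curtis_oracle(profiles[i], profiles[j])
                assert abs(dm.values[i, j] - expected) < 1e-12


def meta_for(habitats, n_rep):
    rows = []
    for h in habitats:
        for r in range(1, n_rep + 1):
            rows.append({"sample_id": f"{h}.{r}", "site_code": h,
                         "layer_label": "1", "biome_class": "soil",
                         "replicate_index": r, "habitat_id": h})
    return bb.SampleMetadata(frame=pd.DataFrame(rows).set_index("sample_id"))


class TestReplicateDistanceTest:
    def test_extreme_separation_passes(self):
        # identical replicates within habitats, disjoint habitats
        counts = pd.DataFrame(
            {"A.1": [1, 0], "A.2": [1, 0], "A.3": [1, 0],
             "B.1": [0, 1], "B.2": [0, 1], "B.3": [0, 1]}, index=["o1", "o2"])
        table = bb.OtuTable(counts=counts, domain_label="bacteria")
        dm = bb.bray_curtis(bb.relative_abundance(table))
        result = bb.replicate_distance_test(dm, meta_for(["A", "B"], 3))
        assert set(result.within_distances) == {0.0}
        assert set(result.between_distances) == {1.0}
        assert result.p_value < 1e-6 and result.passed

    def test_matches_welch_closed_form(self):
        """One-sided Welch statistic and p agree with the closed form."""
        within = [0.10, 0.12, 0.09, 0.11]
        between = [0.50, 0.55, 0.45, 0.52]
        m1, m2 = np.mean(within), np.mean(between)
        v1 = np.var(within, ddof=1) / len(within)
        v2 = np.var(between, ddof=1) / len(between)
        t = (m1 - m2) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (len(within) - 1)
                               + v2**2 / (len(between) - 1))
        from scipy.stats import t as t_dist, ttest_ind
        p = t_dist.cdf(t, df)
        t_impl, p_impl = ttest_ind(within, between, equal_var=False,
                                   alternative="less")
        assert abs(t_impl - t) < 1e-9
        assert abs(p_impl - p) < 1e-9

    def test_permuted_labels_type_one_error_calibrated(self):
        """Random replicate labels: the test passes at alpha=0.05 in about
        5% of simulations (no more than ~9% over 300 runs)."""
        rng = np.random.default_rng(0)
        meta = meta_for(["A", "B", "C", "D", "E"], 3)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            counts = pd.DataFrame(rng.integers(1, 200, (30, 15)),
                                  columns=meta.sample_ids)
            dm = bb.bray_curtis(bb.relative_abundance(counts))
            result = bb.replicate_distance_test(dm, meta, alpha=0.05)
            hits += result.passed
        assert hits / n_sim <= 0.09

    def test_single_replicate_habitat_warns(self):
        meta = meta_for(["A", "B"], 3)
        frame = meta.frame.drop(index=["B.2", "B.3"])
        frame.loc["B.1", "replicate_index"] = 1
        meta = bb.SampleMetadata(frame=frame)
        counts = pd.DataFrame(
            np.arange(8).reshape(2, 4) + 1,
            columns=["A.1", "A.2", "A.3", "B.1"], index=["o1", "o2"])
        dm = bb.bray_curtis(bb.relative_abundance(counts))
        with pytest.warns(UserWarning, match="single replicate"):
            bb.replicate_distance_test(dm, meta)

    def test_no_within_pairs_rejected(self):
        meta = meta_for(["A", "B"], 1)
        counts = pd.DataFrame([[1, 2], [3, 4]], columns=["A.1", "B.1"])
        dm = bb.bray_curtis(bb.relative_abundance(counts))
        with pytest.raises(ValueError):
            bb.replicate_distance_test(dm, meta)

    def test_passes_on_default_synthetic_data(self, dataset):
        for table in dataset.tables.values():
            dm = bb.bray_curtis(bb.relative_abundance(table))
            result = bb.replicate_distance_test(dm, dataset.metadata,
                                                alpha=0.001)
            assert result.passed


class TestPooling:
    def test_detection_in_any_replicate_survives(self):
        table = make_table([[1, 0, 0]], samples=["A.1", "A.2", "A.3"])
        pooled = bb.pool_replicates(table, meta_for(["A"], 3))
        assert pooled.counts.at["OTU1", "A"] == 1

    def test_all_zero_replicates_pool_to_zero(self):
        table = make_table([[0, 0, 0], [1, 1, 1]],
                           samples=["A.1", "A.2", "A.3"])
        pooled = bb.pool_replicates(table, meta_for(["A"], 3))
        assert pooled.counts.at["OTU1", "A"] == 0

    @given(arrays(np.int64, (6, 6), elements=st.integers(0, 100)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conserves_totals_and_replicate_order(self, counts):
        counts[0] += 1
        meta = meta_for(["A", "B"], 3)
        table = bb.OtuTable(
            counts=pd.DataFrame(counts, columns=meta.sample_ids),
            domain_label="bacteria")
        pooled = bb.pool_replicates(table, meta)
        assert pooled.counts.to_numpy().sum() == counts.sum()
        shuffled = bb.OtuTable(
            counts=table.counts[list(reversed(meta.sample_ids))],
            domain_label="bacteria")
        pd.testing.assert_frame_equal(
            bb.pool_replicates(shuffled, meta).counts, pooled.counts)

    def test_sample_missing_from_metadata_rejected(self):
        table = make_table([[1, 2]], samples=["A.1", "Z.9"])
        with pytest.raises(KeyError):
            bb.pool_replicates(table, meta_for(["A"], 3))
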