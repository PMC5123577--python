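"""Replicate quality control and pooling.

Field replicates are only pooled after verifying that community composition
is more similar within habitats (replicate pairs) than between habitats,
using a one-sided Welch t-test on Bray-Curtis dissimilarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_ind

from .core_io import OtuTable, SampleMetadata


def relative_abundance(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions: each column divided by its read total."""
    counts = table.counts if isinstance(table, OtuTable) else table
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero)}")
    return counts / totals


@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis dissimilarity matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("Bray-Curtis values must lie in [0, 1]")
        self.values = v

    def between(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis(profiles: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); 0 for identical profiles,
    1 for disjoint supports. Profiles must be non-negative and no column may
    be all-zero (the dissimilarity is undefined for two empty profiles).
    """
    x = profiles.to_numpy(dtype=float).T
    if np.any(x < 0):
        raise ValueError("profiles must be non-negative")
    if np.any(x.sum(axis=1) == 0):
        bad = [c for c, s in zip(profiles.columns, x.sum(axis=1)) if s == 0]
        raise ValueError(f"all-zero profile(s): {bad}")
    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(ids=list(profiles.columns),
                          values=squareform(condensed))


@dataclass
class ReplicateTestResult:
    within_distances: list[float]
    between_distances: list[float]
    t_statistic: float
    p_value: float
    alpha: float
    passed: bool

    @property
    def mean_within(self) -> float:
        return float(np.mean(self.within_distances))

    @property
    def mean_between(self) -> float:
        return float(np.mean(self.between_distances))


def replicate_distance_test(dm: DistanceMatrix, meta: SampleMetadata,
                            alpha: float = 0.001) -> ReplicateTestResult:
    """One-sided Welch t-test: within-habitat < between-habitat dissimilarity.

    Within pairs are replicate pairs of the same habitat; between pairs are
    every other sample pair (different depth or site). Habitats with a single
    replicate contribute no within pairs and trigger a warning.
    """
    habitats = [meta.habitat_of(s) for s in dm.ids]
    counts = pd.Series(habitats).value_counts()
    singles = counts.index[counts == 1].tolist()
    if singles:
        warnings.warn(f"habitat(s) with a single replicate: {singles}",
                      stacklevel=2)
    within, between = [], []
    n = len(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = dm.values[i, j]
            (within if habitats[i] == habitats[j] else between).append(float(d))
    if not within:
        raise ValueError("no within-habitat replicate pairs")
    t, p = ttest_ind(within, between, equal_var=False, alternative="less")
    passed = bool(np.mean(within) < np.mean(between) and p < alpha)
    return ReplicateTestResult(within_distances=within,
                               between_distances=between,
                               t_statistic=float(t), p_value=float(p),
                               alpha=alpha, passed=passed)


def pool_replicates(table: OtuTable, meta: SampleMetadata) -> OtuTable:
    """Sum counts over the replicates of each habitat (63 -> 21 columns).

    Pooling by summation increases effective sequencing depth, so an OTU
    detected in any replicate is detected in the pooled habitat.
    """
    habitat_of = {s: meta.habitat_of(s) for s in table.sample_ids}
    pooled = table.counts.T.groupby(
        table.counts.columns.map(habitat_of)).sum().T
    pooled = pooled.sort_index(axis=1)
    return OtuTable(counts=pooled, domain_label=table.domain_label)
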