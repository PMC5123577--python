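"""Readers, writers and validated containers for OTU tables, sample metadata
and taxonomy, plus writers for all pipeline products.

All tables are tab-separated text. Writers emit a canonical form (OTUs and
samples sorted lexicographically) so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import BIOME_CLASSES, DOMAINS, habitat_id

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


class FormatError(ValueError):
    """Malformed input file (missing header, wrong columns, empty file)."""


class UniquenessError(ValueError):
    """Duplicate identifier where uniqueness is required."""


class VocabularyError(ValueError):
    """Value outside a controlled vocabulary (e.g. biome class)."""


class TaxonomyConflictError(ValueError):
    """Same OTU id mapped to two different lineages."""


# ---------------------------------------------------------------------------
# OTU table

@dataclass
class OtuTable:
    """Integer count matrix of OTUs (rows) x samples (columns).

    ``domain_label`` is one of bacteria/fungi/archaea, or ``merged`` for the
    cross-domain table used in network inference.
    """

    counts: pd.DataFrame
    domain_label: str
    zero_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.domain_label not in (*DOMAINS, "merged"):
            raise VocabularyError(f"unknown domain label {self.domain_label!r}")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise UniquenessError(f"duplicate OTU ids: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise UniquenessError(f"duplicate sample ids: {dups[:5]}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers (read counts)")
        self.counts = self.counts.astype(np.int64)
        zero = self.counts.columns[self.counts.sum(axis=0) == 0]
        self.zero_samples = list(zero)
        if self.zero_samples:
            log.warning(
                "%s table: all-zero sample column(s) %s",
                self.domain_label, self.zero_samples,
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def read_otu_table(path: str | Path, domain_label: str) -> OtuTable:
    """Read a tab-separated OTU table (first column OTU id, header = samples)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file or missing header")
    cols = header.rstrip("\n").split("\t")
    if len(cols) < 2:
        raise FormatError(f"{path}: header must name at least one sample")
    samples = cols[1:]
    if len(set(samples)) != len(samples):
        raise UniquenessError(f"{path}: duplicate sample ids in header")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"{path}: {exc}") from exc
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric count in column {col!r}")
    return OtuTable(counts=frame, domain_label=domain_label)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    canonical = table.counts.sort_index(axis=0).sort_index(axis=1)
    canonical.to_csv(path, sep="\t", index_label="otu_id")


# ---------------------------------------------------------------------------
# Sample metadata

METADATA_COLUMNS = ("sample_id", "site_code", "layer_label",
                    "biome_class", "replicate_index")


@dataclass
class SampleMetadata:
    """Site/layer/biome/replicate annotations; index is sample_id."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"site_code", "layer_label", "biome_class", "replicate_index"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"metadata missing columns {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise UniquenessError("duplicate sample_id in metadata")
        bad = set(self.frame["biome_class"]) - set(BIOME_CLASSES)
        if bad:
            raise VocabularyError(f"unknown biome_class values {sorted(bad)}")
        if "habitat_id" not in self.frame.columns:
            self.frame = self.frame.assign(
                habitat_id=[
                    habitat_id(s, str(l))
                    for s, l in zip(self.frame["site_code"],
                                    self.frame["layer_label"])
                ]
            )
        key = list(zip(self.frame["habitat_id"], self.frame["replicate_index"]))
        if len(set(key)) != len(key):
            raise UniquenessError("duplicate (habitat_id, replicate_index)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def habitats(self) -> list[str]:
        return sorted(self.frame["habitat_id"].unique())

    def habitat_of(self, sample_id: str) -> str:
        try:
            return self.frame.at[sample_id, "habitat_id"]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in metadata") from None


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                                   "layer_label": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty metadata file") from None
    if "sample_id" not in frame.columns:
        raise FormatError(f"{path}: missing sample_id column")
    frame = frame.set_index("sample_id")
    frame["replicate_index"] = frame["replicate_index"].astype(int)
    if (frame["replicate_index"] < 1).any():
        raise ValueError(f"{path}: replicate_index must be >= 1")
    return SampleMetadata(frame=frame)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.frame.sort_index()
    cols = ["site_code", "layer_label", "biome_class",
            "replicate_index", "habitat_id"]
    out[cols].to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Taxonomy

@dataclass
class TaxonomyMap:
    """otu_id -> (domain, rank path), e.g. ("fungi", ("Ascomycota", "Sordariomycetes")).

    Unresolved ranks carry the explicit ``unclassified`` token.
    """

    lineages: dict[str, tuple[str, tuple[str, ...]]]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def domain(self, otu_id: str) -> str:
        return self.lineages[otu_id][0]

    def rank_path(self, otu_id: str) -> tuple[str, ...]:
        return self.lineages[otu_id][1]

    def taxon_at(self, otu_id: str, level: int) -> str:
        """Taxon name at 0-based rank level; ``unclassified <domain>`` fallback."""
        domain, path = self.lineages[otu_id]
        if level < len(path) and path[level] != UNCLASSIFIED:
            return path[level]
        return f"{UNCLASSIFIED} {domain}"


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read otu_id <tab> domain <tab> semicolon-joined rank path."""
    lineages: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("otu_id\t")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 columns")
            otu_id, domain = parts[0], parts[1]
            raw = parts[2] if len(parts) > 2 else ""
            ranks = tuple(r.strip() or UNCLASSIFIED
                          for r in raw.split(";")) if raw.strip() else (UNCLASSIFIED,)
            if otu_id in lineages and lineages[otu_id] != (domain, ranks):
                raise TaxonomyConflictError(
                    f"{path}:{lineno}: conflicting lineage for {otu_id!r}")
            lineages[otu_id] = (domain, ranks)
    return TaxonomyMap(lineages=lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tdomain\tlineage\n")
        for otu_id in sorted(tax.lineages):
            domain, ranks = tax.lineages[otu_id]
            fh.write(f"{otu_id}\t{domain}\t{';'.join(ranks)}\n")


# ---------------------------------------------------------------------------
# Product writers

def write_long_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Long-format TSV with deterministic row order (sorted by all columns)."""
    out = frame.sort_values(list(frame.columns)).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_newick(dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")


def write_edge_list(network, path: str | Path) -> None:
    """Edge list TSV: otu_a, otu_b, rho, p (endpoints sorted within a row)."""
    rows = []
    for a, b, attrs in network.graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append((a, b, attrs["rho"], attrs["p"]))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("otu_a\totu_b\trho\tp\n")
        for a, b, rho, p in rows:
            fh.write(f"{a}\t{b}\t{rho:.10g}\t{p:.10g}\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_graphml(network, path: str | Path) -> None:
    import networkx as nx

    graph = network.graph.copy()
    for node in graph.nodes:
        graph.nodes[node]["degree"] = graph.degree[node]
    # networkx writes attributes it finds on nodes/edges; rho is already set
    buf = io.BytesIO()
    nx.write_graphml(graph, buf, named_key_ids=True)
    Path(path).write_bytes(buf.getvalue())


def write_products(product, path: str | Path, fmt: str) -> None:
    """Dispatch writer: fmt in {newick, graphml, edgelist, long_tsv, otu_tsv}."""
    writers = {
        "newick": write_newick,
        "graphml": write_graphml,
        "edgelist": write_edge_list,
        "long_tsv": write_long_table,
        "otu_tsv": write_otu_table,
    }
    if fmt not in writers:
        raise FormatError(f"unsupported output format {fmt!r}")
    writers[fmt](product, path)
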