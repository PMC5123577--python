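"""Habitat-breadth classification of OTUs over pooled habitats.

An OTU detected in every (or nearly every) habitat along the gradient is a
habitat generalist; one detected in exactly one pooled habitat (one site and
depth) is a habitat specialist; everything in between is intermediate. The
operative generalist rule is occurrence >= 16 of the 21 pooled habitats.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import OtuTable, TaxonomyMap
from .replicate_qc import relative_abundance

GENERALIST = "generalist"
INTERMEDIATE = "intermediate"
SPECIALIST = "specialist"


@dataclass
class OccurrenceProfile:
    otu_id: str
    habitats_detected: frozenset[str]
    breadth_class: str | None = None

    @property
    def occurrence(self) -> int:
        return len(self.habitats_detected)


def occurrence_profile(table: OtuTable,
                       min_count: int = 1) -> list[OccurrenceProfile]:
    """Presence profile per OTU: detected in habitat h iff pooled count >= min_count."""
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    detected = table.counts >= min_count
    return [
        OccurrenceProfile(
            otu_id=otu,
            habitats_detected=frozenset(detected.columns[detected.loc[otu]]),
        )
        for otu in table.otu_ids
    ]


def classify_breadth(profiles: list[OccurrenceProfile],
                     n_habitats: int = 21,
                     generalist_min: int = 16) -> list[OccurrenceProfile]:
    """Assign breadth classes; OTUs with zero occurrence are dropped.

    occurrence >= generalist_min -> generalist; occurrence == 1 ->
    specialist; otherwise intermediate.
    """
    if generalist_min <= 1:
        raise ValueError("generalist_min must exceed 1 (classes would collide)")
    classified = []
    for prof in profiles:
        occ = prof.occurrence
        if occ > n_habitats:
            raise ValueError(
                f"{prof.otu_id}: occurrence {occ} exceeds n_habitats {n_habitats}")
        if occ == 0:
            continue
        if occ >= generalist_min:
            cls = GENERALIST
        elif occ == 1:
            cls = SPECIALIST
        else:
            cls = INTERMEDIATE
        classified.append(OccurrenceProfile(prof.otu_id,
                                            prof.habitats_detected, cls))
    return classified


def breadth_summary(profiles: list[OccurrenceProfile], table: OtuTable,
                    tax: TaxonomyMap) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long tables backing the generalist and specialist dot plots.

    Generalists: one row per (OTU, habitat) with relative abundance and a
    ``detected`` flag (False rows are the explicit non-detection marks).
    Specialists: one row per OTU with its single habitat, grouped by domain
    and class-level taxon.
    """
    rel = relative_abundance(table)
    gen_rows, spec_rows = [], []
    for prof in profiles:
        if prof.breadth_class is None:
            raise ValueError("breadth classes must be assigned first")
        taxon = tax.taxon_at(prof.otu_id, 1)
        domain = tax.domain(prof.otu_id)
        if prof.breadth_class == GENERALIST:
            for habitat in table.sample_ids:
                gen_rows.append({
                    "otu_id": prof.otu_id,
                    "domain": domain,
                    "taxon": taxon,
                    "habitat_id": habitat,
                    "relative_abundance": float(rel.at[prof.otu_id, habitat]),
                    "detected": habitat in prof.habitats_detected,
                })
        elif prof.breadth_class == SPECIALIST:
            (habitat,) = prof.habitats_detected
            spec_rows.append({
                "otu_id": prof.otu_id,
                "domain": domain,
                "taxon": taxon,
                "habitat_id": habitat,
                "relative_abundance": float(rel.at[prof.otu_id, habitat]),
            })
    columns_g = ["otu_id", "domain", "taxon", "habitat_id",
                 "relative_abundance", "detected"]
    columns_s = columns_g[:-1]
    generalists = pd.DataFrame(gen_rows, columns=columns_g)
    specialists = pd.DataFrame(spec_rows, columns=columns_s)
    generalists = generalists.sort_values(
        ["otu_id", "habitat_id"]).reset_index(drop=True)
    specialists = specialists.sort_values(
        ["domain", "taxon", "habitat_id", "otu_id"]).reset_index(drop=True)
    return generalists, specialists
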