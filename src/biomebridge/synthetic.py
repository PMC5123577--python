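"""Synthetic OTU tables with the statistical structure the pipeline assumes.

The generator emulates the study design — 21 habitats (5 soil sites plus
lake water and sediments, sub-sampled by depth) x 3 replicates — and plants
known structure so every downstream stage has ground truth: habitat
generalists (expected nonzero abundance everywhere), specialists (one
habitat only), habitat-block enrichment driving the soil-vs-lake clustering
signal, overdispersed replicates, and positively correlated OTU pairs
sharing a latent abundance driver.

Abundance model: log-normal expected abundances per OTU x habitat,
Dirichlet replicate-level perturbation, multinomial read sampling at fixed
depth per sample and domain. Structural zeros (specialists outside their
habitat) are preserved exactly by the multinomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import design
from .core_io import OtuTable, SampleMetadata, TaxonomyMap

DOMAIN_PREFIX = {"bacteria": "bac", "fungi": "fun", "archaea": "arc"}

#: synthetic lineage pools (phylum -> classes/orders), one per domain
LINEAGE_POOL = {
    "bacteria": {
        "Actinobacteria": ["Actinomycetales", "Acidimicrobiales"],
        "Proteobacteria": ["Alphaproteobacteria", "Betaproteobacteria"],
        "Acidobacteria": ["Gp16", "Gp1"],
        "Firmicutes": ["Bacilli"],
        "Verrucomicrobia": ["Spartobacteria"],
        "Chloroflexi": ["Anaerolineae"],
        "Bacteroidetes": ["Sphingobacteriia"],
        "Cyanobacteria": ["Nostocales"],
    },
    "fungi": {
        "Ascomycota": ["Dothideomycetes", "Leotiomycetes", "Sordariomycetes"],
        "Basidiomycota": ["Agaricomycetes", "Tremellomycetes"],
    },
    "archaea": {
        "Thaumarchaeota": ["Nitrososphaerales"],
        "Euryarchaeota": ["Methanobacteriales", "Methanosarcinales",
                          "Thermoplasmatales"],
    },
}


def _per_domain(value) -> dict[str, int]:
    if isinstance(value, dict):
        return {d: int(value.get(d, 0)) for d in design.DOMAINS}
    return {d: int(value) for d in design.DOMAINS}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic community.

    Counts (``n_otus``, ``n_generalists``, ``n_specialists``) may be a
    single int applied to every domain or a per-domain dict. ``dispersion``
    is the Dirichlet replicate-noise scale (0 = replicates exactly at the
    habitat expectation); ``block_effect`` multiplies an OTU's expected
    abundance inside its preferred habitat block; planted correlated pairs
    share a latent log-scale factor sized to reach ``corr_strength`` rank
    correlation.
    """

    n_habitats: int = 21
    n_replicates: int = 3
    reads_per_sample: int = 5000
    n_otus: dict[str, int] | int = field(
        default_factory=lambda: {"bacteria": 120, "fungi": 90, "archaea": 60})
    n_generalists: dict[str, int] | int = field(
        default_factory=lambda: {"bacteria": 3, "fungi": 6, "archaea": 3})
    n_specialists: dict[str, int] | int = field(
        default_factory=lambda: {"bacteria": 25, "fungi": 20, "archaea": 12})
    habitat_blocks: tuple[tuple[str, ...], ...] = design.DEFAULT_BLOCKS
    block_effect: float = 6.0
    n_corr_pairs: int = 10
    corr_strength: float = 0.9
    dispersion: float = 0.002
    base_sigma: float = 1.5      # log-scale spread of background abundances
    habitat_sigma: float = 0.6   # log-scale habitat-to-habitat noise
    planted_mu: float = 1.5      # log-scale mean abundance of planted OTUs
    planted_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_otus = _per_domain(self.n_otus)
        self.n_generalists = _per_domain(self.n_generalists)
        self.n_specialists = _per_domain(self.n_specialists)
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be > 0")
        if not 0 < self.corr_strength <= 1:
            raise ValueError("corr_strength must lie in (0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.block_effect <= 0:
            raise ValueError("block_effect must be > 0")
        for d in design.DOMAINS:  # empty domains plant nothing
            if self.n_otus[d] == 0:
                self.n_generalists[d] = 0
                self.n_specialists[d] = 0
        for d in design.DOMAINS:
            if self.n_generalists[d] + self.n_specialists[d] > self.n_otus[d]:
                raise ValueError(
                    f"{d}: n_generalists + n_specialists exceeds n_otus")
        background = sum(
            self.n_otus[d] - self.n_generalists[d] - self.n_specialists[d]
            for d in design.DOMAINS)
        if 2 * self.n_corr_pairs > background:
            raise ValueError("not enough background OTUs for n_corr_pairs")

    def habitats(self) -> list[str]:
        if self.n_habitats == 21:
            return design.default_habitats()
        return [f"H{i + 1:02d}" for i in range(self.n_habitats)]

    def site_blocks(self) -> dict[str, int]:
        """site -> block index (generic designs split sites evenly in 3)."""
        if self.n_habitats == 21:
            return {s: design.block_of_site(s, self.habitat_blocks)
                    for s in design.SITE_LAYERS}
        sites = sorted({h.split("-", 1)[0] for h in self.habitats()})
        return {s: min(i * 3 // len(sites), 2) for i, s in enumerate(sites)}


@dataclass
class GroundTruth:
    """Planted structure: per-OTU class, per-pair flags, block membership."""

    frame: pd.DataFrame            # index otu_id: domain, true_class,
    #                                specialist_habitat, block, corr_pair
    pairs: list[tuple[str, str]]   # planted positively correlated pairs
    blocks: dict[str, int]         # site -> block index

    def planted(self, true_class: str) -> list[str]:
        return list(self.frame.index[self.frame["true_class"] == true_class])


def generate_expected_profiles(
        spec: SyntheticSpec,
        rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Expected relative-abundance matrix (OTU x habitat) plus ground truth.

    Each domain's habitat columns are renormalized to sum to 1 (each domain
    is sequenced as its own amplicon pool). With ``block_effect == 1`` and
    no planted pairs or specialists, habitat columns are i.i.d.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    habitats = spec.habitats()
    H = len(habitats)
    site_block = spec.site_blocks()
    habitat_block = np.array(
        [site_block[h.split("-", 1)[0]] for h in habitats])

    frames = []
    truth_rows = []
    background_ids: list[str] = []
    for dom in design.DOMAINS:
        n = spec.n_otus[dom]
        if n == 0:
            continue
        n_gen, n_spec = spec.n_generalists[dom], spec.n_specialists[dom]
        ids = [f"{DOMAIN_PREFIX[dom]}_OTU{i + 1:04d}" for i in range(n)]
        classes = ([ "generalist"] * n_gen + ["specialist"] * n_spec
                   + ["background"] * (n - n_gen - n_spec))
        mu = np.where(
            np.array(classes) == "background",
            rng.normal(0.0, spec.base_sigma, n),
            rng.normal(spec.planted_mu, spec.planted_sigma, n))
        log_abund = mu[:, None] + rng.normal(0.0, spec.habitat_sigma, (n, H))
        # habitat-block enrichment for every multi-habitat OTU
        pref_block = rng.integers(0, 3, n)
        boost = (habitat_block[None, :] == pref_block[:, None])
        log_abund = log_abund + np.log(spec.block_effect) * boost
        expected = np.exp(log_abund)
        spec_habitat = rng.integers(0, H, n)
        for i, cls in enumerate(classes):
            if cls == "specialist":
                mask = np.zeros(H)
                mask[spec_habitat[i]] = 1.0
                expected[i] *= mask
        for i, cls in enumerate(classes):
            truth_rows.append({
                "otu_id": ids[i], "domain": dom, "true_class": cls,
                "specialist_habitat":
                    habitats[spec_habitat[i]] if cls == "specialist" else "",
                "block": int(pref_block[i]) if cls != "specialist" else -1,
                "corr_pair": -1,
            })
            if cls == "background":
                background_ids.append(ids[i])
        frames.append(pd.DataFrame(expected, index=ids, columns=habitats))

    profiles = pd.concat(frames, axis=0)
    truth_frame = pd.DataFrame(truth_rows).set_index("otu_id")

    # planted correlated pairs: drawn from the background pool, made
    # abundant everywhere, sharing one latent habitat factor per pair
    pairs: list[tuple[str, str]] = []
    if spec.n_corr_pairs > 0:
        r_pearson = 2 * math.sin(math.pi * spec.corr_strength / 6)
        r_pearson = min(r_pearson, 0.999)
        lam = spec.habitat_sigma * math.sqrt(r_pearson / (1 - r_pearson))
        members = background_ids[:2 * spec.n_corr_pairs]
        for k in range(spec.n_corr_pairs):
            a, b = members[2 * k], members[2 * k + 1]
            z = rng.normal(0.0, 1.0, H)
            for m in (a, b):
                mu_m = rng.normal(spec.planted_mu + 0.5, 0.3)
                log_a = (mu_m + lam * z
                         + rng.normal(0.0, spec.habitat_sigma, H))
                profiles.loc[m] = np.exp(log_a)
                truth_frame.at[m, "true_class"] = "corr_member"
                truth_frame.at[m, "corr_pair"] = k
                truth_frame.at[m, "block"] = -1
            pairs.append((a, b))

    # renormalize per domain: each domain's habitat column sums to 1
    for dom in design.DOMAINS:
        prefix = DOMAIN_PREFIX[dom] + "_"
        rows = profiles.index.str.startswith(prefix)
        if rows.any():
            block = profiles.loc[rows]
            totals = block.sum(axis=0)
            if (totals == 0).any():
                raise ValueError(f"{dom}: habitat column with zero total")
            profiles.loc[rows] = block / totals

    truth = GroundTruth(frame=truth_frame, pairs=pairs,
                        blocks=spec.site_blocks())
    return profiles, truth


def sample_counts(
        expected: pd.DataFrame, spec: SyntheticSpec,
        rng: np.random.Generator | None = None,
) -> tuple[dict[str, OtuTable], SampleMetadata]:
    """Draw replicate-level counts from the expected profiles.

    For each habitat x replicate, replicate proportions are a Dirichlet
    perturbation of the habitat expectation with concentration
    1/dispersion (dispersion 0 = no replicate noise), then
    ``reads_per_sample`` reads are drawn multinomially. Counts are split
    into per-domain tables; deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed + 1))
    habitats = list(expected.columns)
    sample_ids = [f"{h}.{r + 1}" for h in habitats
                  for r in range(spec.n_replicates)]

    tables: dict[str, OtuTable] = {}
    for dom in design.DOMAINS:
        prefix = DOMAIN_PREFIX[dom] + "_"
        rows = expected.index.str.startswith(prefix)
        if not rows.any():
            continue
        block = expected.loc[rows]
        counts = np.zeros((block.shape[0], len(sample_ids)), dtype=np.int64)
        col = 0
        for h in habitats:
            p = block[h].to_numpy(dtype=float)
            if p.sum() <= 0:
                raise ValueError(f"zero-sum habitat column {h!r}")
            p = p / p.sum()
            support = p > 0
            for _ in range(spec.n_replicates):
                if spec.dispersion > 0:
                    p_rep = np.zeros_like(p)
                    p_rep[support] = rng.dirichlet(
                        p[support] / spec.dispersion)
                else:
                    p_rep = p
                counts[:, col] = rng.multinomial(spec.reads_per_sample, p_rep)
                col += 1
        tables[dom] = OtuTable(
            counts=pd.DataFrame(counts, index=block.index,
                                columns=sample_ids),
            domain_label=dom)

    meta_rows = []
    for h in habitats:
        site, layer = (h.split("-", 1) if "-" in h else (h, "1"))
        for r in range(spec.n_replicates):
            meta_rows.append({
                "sample_id": f"{h}.{r + 1}",
                "site_code": site,
                "layer_label": layer,
                "biome_class": design.BIOME_OF_SITE.get(site, "soil"),
                "replicate_index": r + 1,
                "habitat_id": h,
            })
    meta = SampleMetadata(frame=pd.DataFrame(meta_rows).set_index("sample_id"))
    return tables, meta


def synthetic_taxonomy(otu_ids: list[str],
                       rng: np.random.Generator) -> TaxonomyMap:
    """Random synthetic lineages (phylum, class/order) per OTU."""
    reverse = {v: k for k, v in DOMAIN_PREFIX.items()}
    lineages = {}
    for otu in otu_ids:
        dom = reverse[otu.split("_", 1)[0]]
        pool = LINEAGE_POOL[dom]
        phylum = str(rng.choice(sorted(pool)))
        klass = str(rng.choice(pool[phylum]))
        lineages[otu] = (dom, (phylum, klass))
    return TaxonomyMap(lineages=lineages)


@dataclass
class SimulatedDataset:
    spec: SyntheticSpec
    expected: pd.DataFrame
    tables: dict[str, OtuTable]
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    truth: GroundTruth


def simulate_dataset(spec: SyntheticSpec) -> SimulatedDataset:
    """Full synthetic dataset from a single seed (sub-streams per stage)."""
    ss = np.random.SeedSequence(spec.seed)
    rng_profiles, rng_counts, rng_tax = (
        np.random.default_rng(child) for child in ss.spawn(3))
    expected, truth = generate_expected_profiles(spec, rng_profiles)
    tables, meta = sample_counts(expected, spec, rng_counts)
    tax = synthetic_taxonomy(list(expected.index), rng_tax)
    return SimulatedDataset(spec=spec, expected=expected, tables=tables,
                            metadata=meta, taxonomy=tax, truth=truth)


def null_spec(n_otus: int = 200, seed: int = 0, **overrides) -> SyntheticSpec:
    """Spec with no planted structure: independent profiles, no blocks,
    no correlated pairs, no specialists — the null for edge calibration."""
    base = SyntheticSpec(
        n_otus={"bacteria": n_otus, "fungi": 0, "archaea": 0},
        n_generalists=0, n_specialists=0,
        n_corr_pairs=0, block_effect=1.0, seed=seed)
    return replace(base, **overrides) if overrides else base


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict[str, str]:
    """Write OTU tables, metadata, taxonomy and ground truth as TSVs."""
    from pathlib import Path

    from .core_io import (write_otu_table, write_sample_metadata,
                          write_taxonomy)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for dom, table in dataset.tables.items():
        p = out / f"otu_{dom}.tsv"
        write_otu_table(table, p)
        paths[dom] = str(p)
    write_sample_metadata(dataset.metadata, out / "metadata.tsv")
    write_taxonomy(dataset.taxonomy, out / "taxonomy.tsv")
    truth = dataset.truth.frame.sort_index()
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index_label="otu_id")
    paths.update(metadata=str(out / "metadata.tsv"),
                 taxonomy=str(out / "taxonomy.tsv"),
                 ground_truth=str(out / "ground_truth.tsv"))
    return paths
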