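"""Sampling design of the terrestrial-freshwater gradient.

Five soil sites around a lake plus lake water and sediments, sub-sampled by
depth into 21 habitats, each sampled in three field replicates (63 samples).
Site codes follow the field labels: dry hill (DH), conifer forest (CF),
flooded area (FL), agricultural soil (AS), shore (SH), lake water (LA),
sediment (SE).
"""

from __future__ import annotations

#: layers per site, in depth order
SITE_LAYERS: dict[str, tuple[str, ...]] = {
    "DH": ("Top", "Med", "Low"),
    "CF": ("Top", "Med", "Low"),
    "FL": ("Top", "Med", "Low"),
    "AS": ("Top", "Low"),
    "SH": ("1", "2", "3", "4", "5"),
    "LA": ("1", "2", "3"),
    "SE": ("Top", "Low"),
}

BIOME_OF_SITE: dict[str, str] = {
    "DH": "soil",
    "CF": "soil",
    "FL": "soil",
    "AS": "soil",
    "SH": "shore",
    "LA": "freshwater",
    "SE": "sediment",
}

BIOME_CLASSES = ("soil", "shore", "freshwater", "sediment")

DOMAINS = ("bacteria", "fungi", "archaea")

#: habitat-similarity blocks mirroring the observed two-cluster / three-group
#: structure: forested soils, open soils, and the shore-to-lake continuum
DEFAULT_BLOCKS: tuple[tuple[str, ...], ...] = (
    ("DH", "CF"),
    ("AS", "FL"),
    ("SH", "LA", "SE"),
)


def habitat_id(site_code: str, layer_label: str) -> str:
    """Composite habitat identifier, e.g. ``DH-Top`` or ``SH-2``."""
    return f"{site_code}-{layer_label}"


def default_habitats() -> list[str]:
    """The 21 habitat ids of the study design, in site/depth order."""
    return [
        habitat_id(site, layer)
        for site in SITE_LAYERS
        for layer in SITE_LAYERS[site]
    ]


def site_of_habitat(habitat: str) -> str:
    return habitat.split("-", 1)[0]


def block_of_site(site: str, blocks=DEFAULT_BLOCKS) -> int:
    for i, group in enumerate(blocks):
        if site in group:
            return i
    raise KeyError(f"site {site!r} not in any block")
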