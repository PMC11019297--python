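"""Body-size contrasts between the two study species.

Field means for breeding adults at the study colony (masked boobies:
28 females, 30 males; red-footed boobies: 9 females, 14 males), taken
with a digital balance (±1 g) and Vernier calipers (±0.01 mm).  The
species contrast is expressed as the percentage by which the larger
species exceeds the smaller, relative to the larger species' mean.
"""

from __future__ import annotations

#: Sex-pooled trait means per species (units in the key names).
TRAIT_MEANS = {
    "body_mass_g": {"masked": 2040.0, "red_footed": 1270.0},
    "culmen_mm": {"masked": 108.0, "red_footed": 90.0},
    "tarsus_mm": {"masked": 62.0, "red_footed": 43.0},
}


def percent_difference(larger: float, smaller: float) -> float:
    """Percent by which ``larger`` exceeds ``smaller``, relative to larger.

    100 × (larger − smaller) / larger; requires larger >= smaller > 0.
    """
    if smaller <= 0 or larger < smaller:
        raise ValueError("need larger >= smaller > 0")
    return 100.0 * (larger - smaller) / larger


def species_size_contrast(trait_means=None) -> dict:
    """Percent size difference between the species for each trait."""
    means = TRAIT_MEANS if trait_means is None else trait_means
    out = {}
    for trait, by_species in means.items():
        values = sorted(by_species.values())
        out[trait] = percent_difference(values[-1], values[0])
    return out
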