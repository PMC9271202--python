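"""Building blocks of the ecological response variables.

Species richness (total, and restricted to forest species — species
recorded at least once at a primary-forest site), carbon pools derived
from measured biomass components, and layered soil organic carbon
stocks with an optional equivalent-soil-mass correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Primary-forest classes defining the forest-species pool.
PRIMARY_FOREST_CLASSES = ("UF", "LF", "LBF")


@dataclass
class CarbonSettings:
    """Carbon fractions of biomass pools and the soil sampling layer.

    Live and dead biomass carry 50% carbon; the litter-pool fraction has
    no assumed default and must be supplied when used (carbon content of
    litter is usually measured directly).  Soils are sampled in 10-cm
    increments.
    """

    live_fraction: float = 0.5
    dead_fraction: float = 0.5
    litter_fraction: float | None = None
    layer_thickness_cm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("live_fraction", "dead_fraction", "litter_fraction"):
            v = getattr(self, name)
            if v is not None and not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


# ---------------------------------------------------------------------------
# Richness
# ---------------------------------------------------------------------------

def species_richness(occurrences: pd.DataFrame, site=None):
    """Number of species with incidence 1 at a site.

    ``occurrences`` is a binary site x species DataFrame (index = site
    IDs).  With ``site=None`` a per-site Series is returned.
    """
    vals = occurrences.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("occurrence matrix must be binary")
    richness = occurrences.sum(axis=1)
    if site is None:
        return richness
    if site not in occurrences.index:
        raise KeyError(f"unknown site {site!r}")
    return int(richness.loc[site])


def forest_species_pool(
    occurrences: pd.DataFrame,
    site_classes: pd.Series,
    primary_classes: Sequence[str] = PRIMARY_FOREST_CLASSES,
) -> list:
    """Species that occur at least once at any primary-forest site."""
    site_classes = site_classes.reindex(occurrences.index)
    primary_sites = site_classes.isin(primary_classes)
    if not primary_sites.any():
        raise ValueError(
            "no primary-forest sites (UF/LF/LBF) in the matrix; the "
            "forest-species filter is undefined"
        )
    present = occurrences.loc[primary_sites.to_numpy()].sum(axis=0) > 0
    return list(occurrences.columns[present])


def forest_species_richness(
    occurrences: pd.DataFrame,
    site_classes: pd.Series,
    site=None,
    primary_classes: Sequence[str] = PRIMARY_FOREST_CLASSES,
):
    """Richness counting only forest species (see :func:`forest_species_pool`).

    Never exceeds total richness at any site.
    """
    pool = forest_species_pool(occurrences, site_classes, primary_classes)
    return species_richness(occurrences[pool], site=site)


# ---------------------------------------------------------------------------
# Carbon pools
# ---------------------------------------------------------------------------

def carbon_pool(component_biomasses: Iterable[float], fraction: float = 0.5) -> float:
    """Carbon stock (Mg C·ha⁻¹) of a biomass pool.

    ``fraction`` x sum of the component biomasses (Mg·ha⁻¹) — e.g. live
    biomass of trees + palms + lianas, or dead biomass of standing dead
    stems + coarse woody debris, each at 50% carbon.
    """
    components = np.asarray(list(component_biomasses), dtype=float)
    if components.size and (components < 0).any():
        raise ValueError("biomass components must be >= 0")
    if not (0 < fraction <= 1):
        raise ValueError("carbon fraction must be in (0, 1]")
    return float(fraction * components.sum())


def soil_carbon_stock(layers: Iterable[tuple[float, float, float]]) -> float:
    """Soil organic carbon stock (Mg C·ha⁻¹) summed over layers.

    Each layer is ``(carbon_content, bulk_density, thickness)`` with the
    carbon content as a mass fraction (0-1), bulk density in g·cm⁻³ and
    thickness in cm.  Per-layer stock = content x density x thickness x
    100 (1 g·cm⁻³ over 1 cm is 100 Mg soil·ha⁻¹).  Order-invariant.
    """
    total = 0.0
    for content, density, thickness in layers:
        if not (0 <= content <= 1):
            raise ValueError(
                f"carbon content {content} outside [0, 1] — was a percentage "
                "passed instead of a mass fraction?"
            )
        if density <= 0 or thickness <= 0:
            raise ValueError("bulk density and thickness must be positive")
        total += content * density * thickness * 100.0
    return total


def equivalent_soil_mass_stocks(
    profiles: dict[str, Sequence[tuple[float, float, float]]],
    reference: str = "lightest",
) -> pd.Series:
    """Fixed-reference-mass soil carbon stocks for comparable profiles.

    Profiles with different bulk densities sample different soil masses
    over the same depth; this correction compares all profiles over the
    same mass of soil.  The reference mass is the minimum
    (``"lightest"``, default) or maximum (``"heaviest"``) total profile
    soil mass across sites; the deepest layer of each profile is trimmed
    (or, for the heaviest reference, extrapolated at the deepest layer's
    concentration) proportionally so the cumulative mass equals the
    reference.
    """
    if reference not in ("lightest", "heaviest"):
        raise ValueError("reference must be 'lightest' or 'heaviest'")
    masses = {}
    for site, layers in profiles.items():
        masses[site] = sum(d * t * 100.0 for _, d, t in layers)  # Mg soil/ha
    ref = min(masses.values()) if reference == "lightest" else max(masses.values())
    out = {}
    for site, layers in profiles.items():
        remaining = ref
        stock = 0.0
        layers = list(layers)
        for i, (content, density, thickness) in enumerate(layers):
            layer_mass = density * thickness * 100.0
            last = i == len(layers) - 1
            take = layer_mass if (layer_mass <= remaining and not last) else remaining
            stock += content * take
            remaining -= take
            if remaining <= 0:
                break
        out[site] = stock
    return pd.Series(out, name="soil_carbon_stock")
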