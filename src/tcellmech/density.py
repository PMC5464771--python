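"""Theoretical ligand surface density of streptavidin-functionalized gels.

Polyacrylamide gels are functionalized by copolymerising a
streptavidin-acrylamide conjugate at a small molar ratio to acrylamide
monomer; biotinylated ligands then bind the streptavidin exposed in a
thin accessible surface layer (~10 nm, about one streptavidin diameter —
deeper molecules are hidden by the ~15 nm pores). The density chain:

1. acrylamide molarity of the mix: ``10 × (% w/v) / M_w`` mol/L
   (M_w = 71.08 g/mol for acrylamide monomer);
2. streptavidin molarity of the mix: molarity × molar ratio (1/100 000);
3. hydrated-gel concentration: mix molarity / swelling factor (the cast
   mix swells ~40% by volume on hydration, factor 1.4), times Avogadro,
   in molecules/µm³;
4. surface density: concentration × accessible depth (10 nm).

Disc diameter and gel thickness cancel exactly — the density depends only
on composition, swelling and accessible depth. Hydrated and mix volumes
are still reported (they are the intermediate quantities one checks
against the casting protocol).

Minority-species density for a coating mixture (e.g. 1 anti-CD3 : 10
anti-CD28+ICAM-1) follows the divide-by-majority-fold convention
(site density / 10), which over-counts relative to a strict partition of
sites (site density × 1/(1+10)); both values are reported, the
divide-by-fold value as primary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from scipy.constants import N_A

__all__ = [
    "GelRecipe",
    "GelGeometry",
    "DensityReport",
    "hydrated_volume",
    "mix_volume",
    "site_density",
    "species_density",
    "estimate_density",
    "ACRYLAMIDE_MOLAR_MASS",
]

#: Molar mass of acrylamide monomer, g/mol.
ACRYLAMIDE_MOLAR_MASS = 71.08


@dataclass(frozen=True)
class GelRecipe:
    """Chemical composition of the polymerization mix.

    ``acrylamide_pct`` is % w/v; ``strept_molar_ratio`` is moles of
    streptavidin-acrylamide per mole of acrylamide monomer (1e-5 in the
    standard protocol). Bis-acrylamide is metadata only — the molar ratio
    is defined against acrylamide alone.
    """

    acrylamide_pct: float
    bis_pct: float = 0.0
    strept_molar_ratio: float = 1e-5
    acrylamide_molar_mass: float = ACRYLAMIDE_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.acrylamide_pct <= 0:
            raise ValueError("acrylamide_pct must be positive")
        if not (0 < self.strept_molar_ratio < 1):
            raise ValueError("strept_molar_ratio must be in (0, 1)")
        if self.acrylamide_molar_mass <= 0:
            raise ValueError("acrylamide_molar_mass must be positive")

    @property
    def acrylamide_molarity(self) -> float:
        """Acrylamide monomer molarity of the mix, mol/L (% w/v → 10 g/L per %)."""
        return 10.0 * self.acrylamide_pct / self.acrylamide_molar_mass


@dataclass(frozen=True)
class GelGeometry:
    """Cast-gel geometry and hydration parameters.

    Disc diameter in mm (standard coverslip: 15), hydrated thickness in µm
    (25–50 after re-hydration), volumetric swelling factor hydrated/mix
    (1.4), accessible surface depth in nm (10).
    """

    disc_diameter_mm: float = 15.0
    hydrated_thickness_um: float = 50.0
    swelling_factor: float = 1.4
    accessible_depth_nm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("disc_diameter_mm", "hydrated_thickness_um", "accessible_depth_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.swelling_factor < 1:
            raise ValueError("swelling_factor must be >= 1 (gels swell on hydration)")


@dataclass(frozen=True)
class DensityReport:
    """Point estimates of the functionalization chain for one recipe."""

    hydrated_volume_ul: float
    mix_volume_ul: float
    site_density: float  # accessible streptavidin, molecules/µm²
    species_densities: Dict[str, float] = field(default_factory=dict)
    species_densities_partition: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, dens in self.species_densities.items():
            if dens > self.site_density * (1 + 1e-12):
                raise ValueError(
                    f"species {name!r} density {dens} exceeds site density {self.site_density}"
                )


def hydrated_volume(geometry: GelGeometry) -> float:
    """Volume of the hydrated gel disc, µL: π (diameter/2)² × thickness."""
    import math

    radius_um = geometry.disc_diameter_mm * 1000.0 / 2.0
    volume_um3 = math.pi * radius_um**2 * geometry.hydrated_thickness_um
    return volume_um3 / 1e9  # µm³ → µL


def mix_volume(hydrated_ul: float, swelling_factor: float = 1.4) -> float:
    """Polymerization-mix volume, µL, given the hydrated volume and swelling."""
    if hydrated_ul <= 0:
        raise ValueError("hydrated volume must be positive")
    if swelling_factor < 1:
        raise ValueError("swelling_factor must be >= 1")
    return hydrated_ul / swelling_factor


def site_density(recipe: GelRecipe, geometry: GelGeometry) -> float:
    """Accessible streptavidin surface density, molecules/µm².

    Mix streptavidin molarity, diluted by the swelling factor, converted
    to molecules/µm³ and multiplied by the accessible depth. Independent
    of disc diameter and thickness (the volumes cancel).
    """
    strept_molarity_mix = recipe.acrylamide_molarity * recipe.strept_molar_ratio
    strept_molarity_gel = strept_molarity_mix / geometry.swelling_factor  # mol/L
    per_um3 = strept_molarity_gel * N_A * 1e-15  # molecules/µm³ (1 L = 1e15 µm³)
    return per_um3 * geometry.accessible_depth_nm * 1e-3  # depth nm → µm


def species_density(
    site_dens: float, coating_fold: float, convention: str = "ratio"
) -> float:
    """Minority-species density for a 1:``coating_fold`` coating mixture.

    ``convention="ratio"`` divides the site density by the majority fold
    (the standard back-of-envelope arithmetic: 30/µm² at 1:10 → 3/µm²);
    ``convention="partition"`` splits total sites 1:(fold), giving
    site_density/(1+fold). The two differ by the factor fold/(1+fold);
    "ratio" is the primary convention, "partition" is reported alongside.
    """
    if site_dens < 0:
        raise ValueError("site density must be non-negative")
    if coating_fold <= 0:
        raise ValueError("coating_fold must be positive")
    if convention == "ratio":
        return site_dens / coating_fold
    if convention == "partition":
        return site_dens / (1.0 + coating_fold)
    raise ValueError(f"unknown convention {convention!r}")


def estimate_density(
    recipe: GelRecipe,
    geometry: GelGeometry,
    coating_folds: Dict[str, float] | None = None,
) -> DensityReport:
    """Full chain: volumes, site density, and per-species densities.

    ``coating_folds`` maps species name → majority fold (e.g.
    ``{"aCD3": 10}`` for a 1:10 anti-CD3 : anti-CD28+ICAM-1 mixture).
    """
    hyd = hydrated_volume(geometry)
    mix = mix_volume(hyd, geometry.swelling_factor)
    dens = site_density(recipe, geometry)
    folds = coating_folds or {}
    return DensityReport(
        hydrated_volume_ul=hyd,
        mix_volume_ul=mix,
        site_density=dens,
        species_densities={
            name: species_density(dens, fold, "ratio") for name, fold in folds.items()
        },
        species_densities_partition={
            name: species_density(dens, fold, "partition") for name, fold in folds.items()
        },
    )
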