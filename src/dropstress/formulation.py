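"""Surfactant-coverage and binder-stoichiometry calculators.

The inverted emulsion is a dispersion of micrometric water droplets in oil.
Given the droplet size distribution and the phase volumes, these calculators
answer two formulation questions:

* how much lipid is needed in the oil phase to cover the total water/oil
  interface, assuming a fixed interfacial footprint per lipid head, and
* how much binder (streptavidin) to dissolve in the water phase so that
  roughly one binder is available per ``lipid_per_binder`` interfacial lipids.

Both are lower bounds: in a real formulation not all lipid partitions at the
interface, so working concentrations sit at or above these values.

Volumes are litres, molar masses g/mol, areas m^2; droplet diameters and
volumes are expressed in micrometres (um, um^3) as is conventional for
emulsion sizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .imaging import SizeDistribution

__all__ = [
    "AVOGADRO",
    "EmulsionRecipe",
    "CoverageResult",
    "water_volume_fraction",
    "mean_droplet_volume",
    "coverage_lipid_concentration",
    "binder_concentration",
]

AVOGADRO = 6.02214076e23  # 1/mol

# reference formulation: 50 uL water emulsified in 800 uL oil, biotinylated
# PE lipid (940 g/mol) at ~1 nm^2 per head, tetrameric streptavidin binder
_DEFAULTS = dict(
    area_per_lipid=1e-18,  # m^2 (1 nm^2)
    M_lipid=940.0,  # g/mol
    M_binder=52_800.0,  # g/mol, streptavidin tetramer (assumed, configurable)
    lipid_per_binder=2000.0,
)


@dataclass(frozen=True)
class EmulsionRecipe:
    """Phase volumes and molecular parameters of an inverted-emulsion batch.

    Parameters
    ----------
    V_w : float
        Dispersed water volume (L).
    V_oil : float
        Continuous oil volume (L).
    V_tot : float, optional
        Total volume (L); defaults to V_w + V_oil.
    area_per_lipid : float
        Interfacial footprint of one lipid head (m^2), default 1 nm^2.
    M_lipid : float
        Lipid molar mass (g/mol), default 940 (16:0 biotinyl PE).
    M_binder : float
        Binder molar mass (g/mol), default 52,800 (streptavidin tetramer;
        an assumption, not a measured value — override if known).
    lipid_per_binder : float
        Stoichiometric ratio of interfacial lipids per binder, default 2000.
    """

    V_w: float
    V_oil: float
    V_tot: float | None = None
    area_per_lipid: float = _DEFAULTS["area_per_lipid"]
    M_lipid: float = _DEFAULTS["M_lipid"]
    M_binder: float = _DEFAULTS["M_binder"]
    lipid_per_binder: float = _DEFAULTS["lipid_per_binder"]

    def __post_init__(self) -> None:
        if self.V_w < 0 or self.V_oil <= 0:
            raise ValueError("phase volumes must be positive (V_w may be 0)")
        if self.V_tot is None:
            object.__setattr__(self, "V_tot", self.V_w + self.V_oil)
        if self.V_w >= self.V_tot and self.V_w > 0:
            raise ValueError("V_w must be smaller than V_tot")
        if self.area_per_lipid <= 0:
            raise ValueError("area_per_lipid must be > 0")
        if self.M_lipid <= 0 or self.M_binder <= 0:
            raise ValueError("molar masses must be > 0")
        if self.lipid_per_binder <= 0:
            raise ValueError("lipid_per_binder must be > 0")


@dataclass(frozen=True)
class CoverageResult:
    """Outcome of the interfacial-coverage calculation."""

    n_droplets: float
    total_area: float  # m^2
    c_lipid_min: float  # mg per mL of oil phase
    phi: float  # water volume fraction (dimensionless)

    def __post_init__(self) -> None:
        if min(self.n_droplets, self.total_area, self.c_lipid_min, self.phi) < 0:
            raise ValueError("coverage results must be non-negative")
        if not self.phi < 1:
            raise ValueError("water volume fraction must be < 1")


def water_volume_fraction(recipe: EmulsionRecipe, reference: str = "oil") -> float:
    """Water volume fraction of the emulsion.

    Parameters
    ----------
    recipe : EmulsionRecipe
    reference : {"oil", "total"}
        Denominator volume. The default "oil" expresses the dispersed volume
        relative to the continuous phase; "total" uses V_tot.
    """
    if reference == "oil":
        V_ref = recipe.V_oil
    elif reference == "total":
        V_ref = recipe.V_tot
    else:
        raise ValueError(f"reference must be 'oil' or 'total', got {reference!r}")
    if V_ref <= 0:
        raise ValueError("reference volume must be > 0")
    return recipe.V_w / V_ref


def mean_droplet_volume(dist: "SizeDistribution | np.ndarray") -> float:
    """Number-weighted mean droplet volume (um^3) from a diameter sample.

    Computes (pi/6) * mean(d^3) over the per-droplet diameters, i.e. the mean
    sphere volume — not the volume of the mean-diameter sphere, which would
    underestimate the third moment for a polydisperse sample.
    """
    diameters = np.asarray(getattr(dist, "diameters", dist), dtype=float)
    if diameters.size == 0:
        raise ValueError("size distribution is empty")
    return float(np.pi / 6.0 * np.mean(diameters**3))


def _sphere_area_from_volume(v: float) -> float:
    """Surface area of the sphere with volume v (units consistent)."""
    r = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
    return 4.0 * np.pi * r**2


def coverage_lipid_concentration(
    recipe: EmulsionRecipe,
    mean_volume: float | None = None,
    dist: "SizeDistribution | np.ndarray | None" = None,
) -> CoverageResult:
    """Minimum lipid concentration to cover the inner-droplet interface.

    The chain: droplet count n = V_w / v_mean; total interfacial area from
    the per-droplet sphere areas (monodisperse-equivalent sphere of volume
    v_mean when only the scalar is given, exact per-droplet summation when a
    full distribution is supplied); lipid moles = area / area_per_lipid / N_A;
    concentration = lipid mass per mL of oil phase.

    Parameters
    ----------
    recipe : EmulsionRecipe
    mean_volume : float, optional
        Mean droplet volume in um^3. Mutually exclusive with ``dist``.
    dist : SizeDistribution or diameter array, optional
        Full diameter sample (um); area is then summed per droplet.

    Returns
    -------
    CoverageResult
        Droplet count, total area (m^2), minimum lipid concentration
        (mg/mL oil) and water volume fraction (vs oil).
    """
    if (mean_volume is None) == (dist is None):
        raise ValueError("provide exactly one of mean_volume or dist")

    if dist is not None:
        diameters = np.asarray(getattr(dist, "diameters", dist), dtype=float)
        if diameters.size == 0:
            raise ValueError("size distribution is empty")
        v_mean_um3 = mean_droplet_volume(diameters)
        # exact per-droplet area, scaled to the batch droplet count
        area_per_droplet_um2 = float(np.mean(np.pi * diameters**2))
    else:
        if mean_volume < 0:
            raise ValueError("mean_volume must be >= 0")
        v_mean_um3 = mean_volume
        area_per_droplet_um2 = (
            _sphere_area_from_volume(v_mean_um3) if v_mean_um3 > 0 else 0.0
        )

    phi = water_volume_fraction(recipe, reference="oil")
    if recipe.V_w == 0 or v_mean_um3 == 0:
        if recipe.V_w > 0 and v_mean_um3 == 0:
            raise ValueError("mean droplet volume must be > 0 when V_w > 0")
        return CoverageResult(n_droplets=0.0, total_area=0.0, c_lipid_min=0.0, phi=phi)

    V_w_um3 = recipe.V_w * 1e15  # 1 L = 1e15 um^3
    n_droplets = V_w_um3 / v_mean_um3
    total_area_m2 = n_droplets * area_per_droplet_um2 * 1e-12  # um^2 -> m^2

    lipid_mol = total_area_m2 / recipe.area_per_lipid / AVOGADRO
    lipid_mg = lipid_mol * recipe.M_lipid * 1e3
    V_oil_mL = recipe.V_oil * 1e3
    c_lipid = lipid_mg / V_oil_mL

    return CoverageResult(
        n_droplets=n_droplets, total_area=total_area_m2, c_lipid_min=c_lipid, phi=phi
    )


def binder_concentration(recipe: EmulsionRecipe, coverage: CoverageResult) -> float:
    """Binder concentration (mg per mL of water phase) for the target stoichiometry.

    Binder moles = interfacial lipid moles / lipid_per_binder; the mass is
    referred to the water phase, where the binder is dissolved.
    """
    if recipe.V_w <= 0:
        raise ValueError("V_w must be > 0 to express a water-phase concentration")
    lipid_mol = coverage.total_area / recipe.area_per_lipid / AVOGADRO
    binder_mol = lipid_mol / recipe.lipid_per_binder
    binder_mg = binder_mol * recipe.M_binder * 1e3
    V_w_mL = recipe.V_w * 1e3
    return binder_mg / V_w_mL
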