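"""Packed-bed transport correlations and physical parameter containers.

The column model is parameterised by three literature correlations commonly
used for liquid chromatography in packed beds:

* axial dispersion from the Chung–Wen correlation,
* external film mass transfer from the Wilson–Geankoplis correlation,
* molecular diffusivity of a solute from the Polson molar-mass scaling.

All public functions take and return SI quantities (m, s, kg, Pa·s).
Configuration files use the bench units of the instrument (mm, µm, µL/min,
mM, s); conversion to SI happens once, in the constructors / loaders below,
so the numerical core never mixes unit systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "FluidProps",
    "SpeciesParams",
    "ColumnParams",
    "WATER_20C",
    "particle_reynolds",
    "molecular_diffusivity",
    "axial_dispersion",
    "film_transfer",
    "interstitial_velocity",
]

# Polson scaling prefactor, m^2/s at unit molar mass (g/mol).
POLSON_PREFACTOR = 2.74e-9


@dataclass(frozen=True)
class FluidProps:
    """Mobile-phase bulk properties.

    Parameters
    ----------
    density : float
        Mass density in kg/m^3.
    viscosity : float
        Dynamic viscosity in Pa·s.
    """

    density: float = 998.0
    viscosity: float = 1.002e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("fluid density and viscosity must be positive")


#: Water at 20 °C, the default mobile-phase approximation for dilute
#: aqueous buffers.
WATER_20C = FluidProps(density=998.0, viscosity=1.002e-3)


@dataclass(frozen=True)
class SpeciesParams:
    """One chromatographic / MS species.

    Parameters
    ----------
    name : str
        Label used in chromatogram columns and reports.
    molar_mass : float
        Molar mass in g/mol.
    pore_access : float
        Size-exclusion distribution coefficient ``K_d`` in [0, 1]:
        1 = fully pore-permeating (small solute), 0 = fully excluded
        (large protein).
    feed_conc : float
        Feed concentration in the declared unit (mM for buffer salts,
        g/L for protein); the column model is linear so the unit only
        needs to be consistent per species.
    diffusivity : float, optional
        Molecular diffusivity in m^2/s. If omitted it is computed from
        the molar mass via the Polson correlation.
    """

    name: str
    molar_mass: float
    pore_access: float = 1.0
    feed_conc: float = 0.0
    diffusivity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")
        if not 0.0 <= self.pore_access <= 1.0:
            raise ValueError(f"pore_access must lie in [0, 1], got {self.pore_access}")
        if self.feed_conc < 0:
            raise ValueError("feed_conc must be nonnegative")

    @property
    def d_m(self) -> float:
        """Molecular diffusivity in m^2/s (given, else Polson estimate)."""
        if self.diffusivity is not None:
            return self.diffusivity
        return molecular_diffusivity(self)

    def with_feed(self, feed_conc: float) -> "SpeciesParams":
        return replace(self, feed_conc=feed_conc)


@dataclass(frozen=True)
class ColumnParams:
    """Geometry and packing of a single SEC column.

    Bench units at the boundary: length and inner diameter in mm,
    particle diameter in µm. Properties expose SI values.
    """

    length_mm: float = 50.0
    inner_diameter_mm: float = 3.0
    particle_diameter_um: float = 80.0
    interstitial_porosity: float = 0.38
    particle_porosity: float = 0.60
    n_cells: int = 60
    dead_time_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.interstitial_porosity < 1.0:
            raise ValueError("interstitial_porosity must lie in (0, 1)")
        if not 0.0 < self.particle_porosity < 1.0:
            raise ValueError("particle_porosity must lie in (0, 1)")
        if self.length_mm <= 0 or self.inner_diameter_mm <= 0:
            raise ValueError("column dimensions must be positive")
        if self.particle_diameter_um <= 0:
            raise ValueError("particle diameter must be positive")
        if self.n_cells < 10:
            raise ValueError("n_cells must be at least 10")
        if self.dead_time_s < 0:
            raise ValueError("dead_time_s must be nonnegative")

    # --- SI geometry -----------------------------------------------------
    @property
    def length(self) -> float:
        """Bed length, m."""
        return self.length_mm * 1e-3

    @property
    def inner_diameter(self) -> float:
        """Inner diameter, m."""
        return self.inner_diameter_mm * 1e-3

    @property
    def particle_diameter(self) -> float:
        """Mean particle diameter d_p, m."""
        return self.particle_diameter_um * 1e-6

    @property
    def particle_radius(self) -> float:
        """Particle radius r_p, m."""
        return 0.5 * self.particle_diameter

    @property
    def cross_section(self) -> float:
        """Empty-tube cross-sectional area, m^2."""
        return math.pi * (0.5 * self.inner_diameter) ** 2

    @property
    def volume(self) -> float:
        """Empty-column volume, m^3."""
        return self.cross_section * self.length

    @property
    def volume_ul(self) -> float:
        """Empty-column volume, µL."""
        return self.volume * 1e9

    @property
    def total_porosity(self) -> float:
        """Total porosity seen by a fully permeating tracer."""
        eps = self.interstitial_porosity
        return eps + (1.0 - eps) * self.particle_porosity

    def accessible_porosity(self, pore_access: float) -> float:
        """Porosity accessible to a species with distribution coefficient K_d."""
        eps = self.interstitial_porosity
        return eps + (1.0 - eps) * self.particle_porosity * pore_access

    def perturbed(self, eps_int_factor: float = 1.0, eps_p_factor: float = 1.0) -> "ColumnParams":
        """Copy with porosities scaled; used for inter-column heterogeneity."""
        return replace(
            self,
            interstitial_porosity=self.interstitial_porosity * eps_int_factor,
            particle_porosity=self.particle_porosity * eps_p_factor,
        )


def interstitial_velocity(flow_rate_ul_min: float, col: ColumnParams) -> float:
    """Interstitial velocity u_int = Q / (A·ε_int), m/s.

    The flow rate is given in bench units (µL/min).
    """
    if flow_rate_ul_min < 0:
        raise ValueError("flow rate must be nonnegative")
    q_si = flow_rate_ul_min * 1e-9 / 60.0  # m^3/s
    return q_si / (col.cross_section * col.interstitial_porosity)


def particle_reynolds(u_int: float, col: ColumnParams, fluid: FluidProps = WATER_20C) -> float:
    """Particle Reynolds number Re_p = u_int·d_p·ρ/η (dimensionless)."""
    if u_int < 0:
        raise ValueError("interstitial velocity must be nonnegative")
    return u_int * col.particle_diameter * fluid.density / fluid.viscosity


def molecular_diffusivity(species: SpeciesParams) -> float:
    """Molecular diffusivity from the Polson molar-mass scaling.

    D_m = 2.74e-9 · M_w^(-1/3) with M_w in g/mol and D_m in m^2/s.
    """
    return POLSON_PREFACTOR * species.molar_mass ** (-1.0 / 3.0)


def axial_dispersion(u_int: float, col: ColumnParams, fluid: FluidProps = WATER_20C) -> float:
    """Axial dispersion coefficient from the Chung–Wen correlation, m^2/s.

    D_ax = u_int·d_p·ε_int / (0.2 + 0.011·(ε_int·Re_p)^0.48)

    At zero velocity the numerator vanishes and 0 is returned, so SMB
    zones with momentarily stopped flow remain representable.
    """
    if u_int < 0:
        raise ValueError("interstitial velocity must be nonnegative")
    if u_int == 0.0:
        return 0.0
    re_p = particle_reynolds(u_int, col, fluid)
    eps = col.interstitial_porosity
    return u_int * col.particle_diameter * eps / (0.2 + 0.011 * (eps * re_p) ** 0.48)


def film_transfer(species: SpeciesParams, u_int: float, col: ColumnParams) -> float:
    """External film mass-transfer coefficient, Wilson–Geankoplis, m/s.

    k_film = 1.09·D_m / (2·r_p·ε_int) · (ε_int·u_int·d_p/D_m)^0.33
    """
    if u_int <= 0:
        raise ValueError("interstitial velocity must be positive")
    d_m = species.d_m
    if d_m <= 0:
        raise ValueError("species diffusivity must be positive")
    eps = col.interstitial_porosity
    pre = 1.09 * d_m / (2.0 * col.particle_radius * eps)
    return pre * (eps * u_int * col.particle_diameter / d_m) ** 0.33
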