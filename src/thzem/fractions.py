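"""Volume fractions and sample geometry for effective-medium analysis.

A protein solution is treated as water with protein inclusions and, around
each globule, a dynamic hydration shell of perturbed water.  The mixing
equations need three volume fractions:

* ``f_p`` — protein fraction in the concentrated solution, where
  essentially all water belongs to hydration shells;
* ``f``   — protein fraction in the dilute solution;
* ``f_sh`` — hydration-shell fraction in the dilute solution, obtained by
  scaling the concentrated solution's aqueous fraction by the
  concentration ratio (shells scale with the number of globules as long
  as they do not overlap).

Mass concentration ``c`` (mg/mL) converts to volume fraction as
``c / (1000 rho)`` with ``rho`` the protein mass density (g/cm^3).
Auxiliary geometry — the equivalent-sphere diameter of a globule from its
molar mass, the shell-to-core volume ratio, and the effective protein
layer thickness in a pressed pellet — lives here too.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.constants import N_A

__all__ = [
    "MaterialSpec",
    "PhaseFractions",
    "PelletSpec",
    "FractionError",
    "ShellOverlapWarning",
    "protein_volume_fraction",
    "shell_volume_fraction",
    "pellet_layer_thickness",
    "equivalent_sphere_diameter",
    "hydration_volume_ratio",
    "DEFAULT_PROTEIN_DENSITY",
    "BSA_MOLECULAR_WEIGHT_KDA",
]

#: serum-albumin-like defaults used throughout the examples
DEFAULT_PROTEIN_DENSITY = 1.41  # g/cm^3
BSA_MOLECULAR_WEIGHT_KDA = 66.5


class FractionError(ValueError):
    """Raised for non-physical concentrations, fractions or geometry."""


class ShellOverlapWarning(UserWarning):
    """Shell fractions high enough that non-overlap of shells is doubtful."""


def protein_volume_fraction(c_mg_per_ml: float, rho_g_per_cm3: float) -> float:
    """Volume fraction occupied by protein at mass concentration ``c``.

    ``f = c / (1000 rho)``: 1 mL of solution holds ``c`` mg of protein of
    density ``rho`` g/cm^3.
    """
    if c_mg_per_ml <= 0:
        raise FractionError(f"concentration must be > 0 mg/mL, got {c_mg_per_ml}")
    if rho_g_per_cm3 <= 0:
        raise FractionError(f"density must be > 0 g/cm^3, got {rho_g_per_cm3}")
    f = c_mg_per_ml / (1000.0 * rho_g_per_cm3)
    if f >= 1.0:
        raise FractionError(
            f"concentration {c_mg_per_ml} mg/mL exceeds the density limit "
            f"{1000 * rho_g_per_cm3} mg/mL (volume fraction {f:.3g} >= 1)"
        )
    return f


def shell_volume_fraction(f_p: float, c_dilute: float, c_conc: float) -> float:
    """Hydration-shell volume fraction in the dilute solution.

    In the concentrated solution the entire aqueous fraction ``1 - f_p`` is
    hydration shell; diluting to ``c_dilute`` scales the shell volume with
    the protein count: ``f_sh = (1 - f_p) * c_dilute / c_conc``.
    """
    if not (0 < f_p < 1):
        raise FractionError(f"f_p must lie in (0, 1), got {f_p}")
    if c_dilute <= 0 or c_conc <= 0:
        raise FractionError("concentrations must be > 0")
    if c_dilute > c_conc:
        raise FractionError(
            f"dilute concentration {c_dilute} exceeds concentrated {c_conc}"
        )
    return (1.0 - f_p) * c_dilute / c_conc


@dataclass(frozen=True)
class MaterialSpec:
    """Protein stock description: concentration, mass density, molar mass."""

    concentration_mg_per_ml: float
    density_g_per_cm3: float = DEFAULT_PROTEIN_DENSITY
    molecular_weight_kDa: float = BSA_MOLECULAR_WEIGHT_KDA

    def __post_init__(self) -> None:
        if self.concentration_mg_per_ml <= 0:
            raise FractionError("concentration must be > 0")
        if self.density_g_per_cm3 <= 0:
            raise FractionError("density must be > 0")
        if self.molecular_weight_kDa <= 0:
            raise FractionError("molecular weight must be > 0")
        # triggers the f < 1 check
        protein_volume_fraction(self.concentration_mg_per_ml, self.density_g_per_cm3)

    @property
    def volume_fraction(self) -> float:
        return protein_volume_fraction(
            self.concentration_mg_per_ml, self.density_g_per_cm3
        )


@dataclass(frozen=True)
class PhaseFractions:
    """The fraction trio the mixing equations consume.

    ``f_p``: protein in the concentrated solution; ``f``: protein in the
    dilute solution; ``f_sh``: hydration shells in the dilute solution.
    """

    f_p: float
    f: float
    f_sh: float

    def __post_init__(self) -> None:
        if not (0 < self.f_p < 1):
            raise FractionError(f"f_p must lie in (0, 1), got {self.f_p}")
        if not (0 < self.f < self.f_p):
            raise FractionError(
                f"f must lie in (0, f_p) = (0, {self.f_p}), got {self.f}"
            )
        if self.f_sh <= 0:
            raise FractionError(f"f_sh must be > 0, got {self.f_sh}")
        if self.f + self.f_sh >= 1:
            raise FractionError(
                f"f + f_sh = {self.f + self.f_sh:.4g} must stay below 1"
            )

    @classmethod
    def from_concentrations(
        cls,
        c_conc: float,
        c_dilute: float,
        density: float = DEFAULT_PROTEIN_DENSITY,
    ) -> "PhaseFractions":
        """Build the trio from the two concentrations and the protein density."""
        f_p = protein_volume_fraction(c_conc, density)
        f = protein_volume_fraction(c_dilute, density)
        f_sh = shell_volume_fraction(f_p, c_dilute, c_conc)
        if f + f_sh > 0.5:
            warnings.warn(
                f"f + f_sh = {f + f_sh:.3g} > 0.5: hydration shells are likely "
                "to overlap, degrading the shell-scaling assumption",
                ShellOverlapWarning,
                stacklevel=2,
            )
        return cls(f_p=f_p, f=f, f_sh=f_sh)

    def scale_protein(self, scale: float) -> "PhaseFractions":
        """Return fractions with the dilute protein fraction ``f`` scaled.

        Useful for studying the dilute limit, where neglecting the protein
        term of the three-phase mixing equation becomes exact.
        """
        if not (0 < scale <= 1):
            raise FractionError(f"scale must lie in (0, 1], got {scale}")
        return PhaseFractions(f_p=self.f_p, f=self.f * scale, f_sh=self.f_sh)


@dataclass(frozen=True)
class PelletSpec:
    """A pressed pellet: protein mass (mg), face area (cm^2), density (g/cm^3)."""

    mass_mg: float
    area_cm2: float
    density_g_per_cm3: float = DEFAULT_PROTEIN_DENSITY

    def __post_init__(self) -> None:
        if self.mass_mg <= 0:
            raise FractionError("pellet mass must be > 0")
        if self.area_cm2 <= 0:
            raise FractionError("pellet area must be > 0")
        if self.density_g_per_cm3 <= 0:
            raise FractionError("density must be > 0")


def pellet_layer_thickness(p: PelletSpec) -> float:
    """Effective protein layer thickness d = m / (rho S), in micrometres.

    This is the thickness the protein in a mixed pellet would occupy if
    collapsed into a dense uniform layer across the pellet face — the ``d``
    needed to convert a pellet transmission spectrum into absorption per
    unit protein path.
    """
    d_cm = (p.mass_mg / 1000.0) / (p.density_g_per_cm3 * p.area_cm2)
    return d_cm * 1e4


def equivalent_sphere_diameter(mw_kDa: float, rho_g_per_cm3: float) -> float:
    """Diameter (nm) of a sphere with the molecule's mass and density.

    V = MW / (N_A rho), d = (6 V / pi)^(1/3).
    """
    if mw_kDa <= 0 or rho_g_per_cm3 <= 0:
        raise FractionError("molecular weight and density must be > 0")
    v_cm3 = (mw_kDa * 1000.0) / (N_A * rho_g_per_cm3)
    d_cm = (6.0 * v_cm3 / math.pi) ** (1.0 / 3.0)
    return d_cm * 1e7


def hydration_volume_ratio(core_diameter_nm: float, shell_thickness_nm: float) -> float:
    """Shell-to-core volume ratio for a spherical core of diameter ``d``.

    ((r + t)^3 - r^3) / r^3 with r = d/2; zero shell thickness gives 0.
    """
    if core_diameter_nm <= 0:
        raise FractionError("core diameter must be > 0")
    if shell_thickness_nm < 0:
        raise FractionError("shell thickness must be >= 0")
    r = core_diameter_nm / 2.0
    return ((r + shell_thickness_nm) ** 3 - r**3) / r**3
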