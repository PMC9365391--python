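"""Closed-form hydrodynamic limits for 1D diffusion of a DNA-bound particle.

Two regimes are modelled for a sphere of radius ``R`` translating along a
DNA axis:

* pure translation (hopping-like motion, no rotational coupling), where the
  friction is the Stokes drag ``f = 6*pi*eta*R``;
* helically coupled sliding, where the particle makes one full turn about
  the DNA axis per helical pitch (3.4 nm, i.e. 10 bp), adding rotational
  drag about its own axis and about the helical axis at offset ``R_oc``.

All frictions are expressed in pN*s/nm, energies in pN*nm, and diffusion
coefficients are returned in um^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HydrodynamicModel",
    "ScanTimeResult",
    "particle_volume",
    "radius_of_gyration",
    "friction_no_rotation",
    "friction_with_rotation",
    "d_limit_no_rotation",
    "d_limit_with_rotation",
    "scan_time",
    "length_per_bp",
    "confinement_length",
    "interval_from_plateau",
]

#: Avogadro constant used in the volume-from-mass conversion (1/mol).
AVOGADRO = 6.023e23

#: Partial specific volume of a typical protein (cm^3/g).
PARTIAL_SPECIFIC_VOLUME = 0.73

#: Water viscosity at room temperature (pN*s/nm^2).
DEFAULT_VISCOSITY = 9e-10

#: Thermal energy k_B*T at 298 K (pN*nm).
DEFAULT_KBT = 4.1143

#: One helical turn of B-form DNA, 10 bp (nm).
HELICAL_PITCH_NM = 3.4

# nm^2/s -> um^2/s
_NM2_TO_UM2 = 1e-6


@dataclass(frozen=True)
class HydrodynamicModel:
    """Physical constants entering the friction formulas.

    Parameters
    ----------
    viscosity : float
        Solvent viscosity in pN*s/nm^2.
    kbt : float
        Thermal energy in pN*nm.
    helical_pitch_nm : float
        DNA length per helical turn in nm.
    """

    viscosity: float = DEFAULT_VISCOSITY
    kbt: float = DEFAULT_KBT
    helical_pitch_nm: float = HELICAL_PITCH_NM

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.kbt <= 0 or self.helical_pitch_nm <= 0:
            raise ValueError("model constants must be positive")


_DEFAULT_MODEL = HydrodynamicModel()


def particle_volume(mass_da: float) -> float:
    """Particle volume in nm^3 from molecular mass in Daltons.

    Uses the partial specific volume 0.73 cm^3/g of a globular protein:
    ``V = 0.73 * 1e21 / N_A * M``.
    """
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    return PARTIAL_SPECIFIC_VOLUME * 1e21 * mass_da / AVOGADRO


def radius_of_gyration(mass_da: float) -> float:
    """Minimal radius (nm) of a sphere with the volume of ``mass_da``.

    ``R_min = (3 V / 4 pi)**(1/3)`` with ``V`` from :func:`particle_volume`.
    """
    v = particle_volume(mass_da)
    return (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)


def friction_no_rotation(radius_nm: float, model: HydrodynamicModel | None = None) -> float:
    """Stokes translational friction ``6*pi*eta*R`` in pN*s/nm."""
    model = model or _DEFAULT_MODEL
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    return 6.0 * math.pi * model.viscosity * radius_nm


def friction_with_rotation(
    radius_nm: float, r_oc_nm: float, model: HydrodynamicModel | None = None
) -> float:
    """Friction of helically coupled sliding in pN*s/nm.

    ``f = 6 pi eta R + (2 pi / pitch)^2 [8 pi eta R^3 + 6 pi eta R R_oc^2]``
    where ``R_oc`` is the distance between the DNA helical axis and the
    particle's centre of mass.
    """
    model = model or _DEFAULT_MODEL
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    if r_oc_nm < 0:
        raise ValueError("R_oc must be non-negative")
    eta = model.viscosity
    rot = (2.0 * math.pi / model.helical_pitch_nm) ** 2 * (
        8.0 * math.pi * eta * radius_nm**3
        + 6.0 * math.pi * eta * radius_nm * r_oc_nm**2
    )
    return 6.0 * math.pi * eta * radius_nm + rot


def d_limit_no_rotation(radius_nm: float, model: HydrodynamicModel | None = None) -> float:
    """Upper diffusion limit (um^2/s) for rotation-free 1D translation."""
    model = model or _DEFAULT_MODEL
    return model.kbt / friction_no_rotation(radius_nm, model) * _NM2_TO_UM2


def d_limit_with_rotation(
    radius_nm: float, r_oc_nm: float, model: HydrodynamicModel | None = None
) -> float:
    """Upper diffusion limit (um^2/s) for helically coupled sliding."""
    model = model or _DEFAULT_MODEL
    return model.kbt / friction_with_rotation(radius_nm, r_oc_nm, model) * _NM2_TO_UM2


@dataclass(frozen=True)
class ScanTimeResult:
    """Traversal time of a DNA segment by 1D diffusion.

    ``t_s`` follows from the continuous relation ``l = sqrt(2 D t)``, i.e.
    ``t = l^2 / (2 D)``.  ``t_alt_s = l^2 / D`` is also reported because the
    factor-2 convention differs between sources; ``t_s`` is the value
    consistent with ``l = sqrt(2 D t)``.
    """

    scan_length_um: float
    d_um2_s: float
    t_s: float
    t_alt_s: float


def scan_time(length_bp: float, nm_per_bp: float, d_um2_s: float) -> ScanTimeResult:
    """Time to scan ``length_bp`` basepairs of stretched DNA by diffusion."""
    if length_bp <= 0 or nm_per_bp <= 0 or d_um2_s <= 0:
        raise ValueError("inputs must be positive")
    l_um = length_bp * nm_per_bp * 1e-3
    return ScanTimeResult(
        scan_length_um=l_um,
        d_um2_s=d_um2_s,
        t_s=l_um**2 / (2.0 * d_um2_s),
        t_alt_s=l_um**2 / d_um2_s,
    )


def length_per_bp(extension_fraction: float, contour_nm_per_bp: float = 0.338) -> float:
    """Effective nm per basepair of a tether held below full extension."""
    if not 0.0 < extension_fraction <= 1.0:
        raise ValueError("extension fraction must be in (0, 1]")
    if contour_nm_per_bp <= 0:
        raise ValueError("contour length per bp must be positive")
    return extension_fraction * contour_nm_per_bp


def confinement_length(msd_limit_um2: float) -> float:
    """Confinement length (um) as the square root of an MSD plateau."""
    if msd_limit_um2 < 0:
        raise ValueError("MSD limit must be non-negative")
    return math.sqrt(msd_limit_um2)


def interval_from_plateau(msd_limit_um2: float) -> float:
    """Reflecting-interval length (um) implied by an MSD plateau.

    The long-lag time-averaged MSD of Brownian motion reflected in an
    interval of length L saturates at ``L^2/6`` (twice the variance of the
    uniform stationary law), so ``L = sqrt(6 * limit)``.
    """
    if msd_limit_um2 < 0:
        raise ValueError("MSD limit must be non-negative")
    return math.sqrt(6.0 * msd_limit_um2)
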