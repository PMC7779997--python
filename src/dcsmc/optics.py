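"""Optical-property containers and diffusion-theory derivations.

Every model in the package (semi-infinite analytical and Monte-Carlo layered)
is parameterised by an absorption coefficient ``mu_a``, a reduced scattering
coefficient ``mu_s'`` and the refractive index of the tissue.  This module
holds the value container plus the small set of closed-form quantities
derived from it: the effective attenuation coefficient
``mu_eff = sqrt(3 mu_a mu_s')`` governing diffuse-light decay with distance,
the extrapolated-boundary lengths ``z0 = 1/mu_s'`` and ``zb = 1.76/mu_s'``
(the 1.76 factor corresponds to a tissue refractive index of 1.37), the
in-medium optical wavenumber ``k0 = 2 pi n / lambda``, and the power-law
scaling of ``mu_s'`` across wavelengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OpticalProperties",
    "effective_attenuation",
    "scale_scattering_power_law",
    "extrapolation_lengths",
    "wavenumber_in_medium",
]

#: Extrapolation-length factor z_b * mu_s' for a tissue/air boundary with
#: tissue refractive index 1.37 (unpolarised Fresnel average).
ZB_FACTOR_N137 = 1.76


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a tissue at a single wavelength.

    Parameters
    ----------
    wavelength_nm : float
        Vacuum wavelength of the source in nanometres.
    mu_a : float
        Absorption coefficient in mm^-1 (>= 0).
    mu_sp : float
        Reduced scattering coefficient mu_s' in mm^-1 (> 0).
    n : float
        Tissue refractive index (>= 1), default 1.37.
    """

    wavelength_nm: float
    mu_a: float
    mu_sp: float
    n: float = 1.37

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength_nm}")
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be non-negative, got {self.mu_a}")
        if self.mu_sp <= 0:
            raise ValueError(f"mu_s' must be positive, got {self.mu_sp}")
        if self.n < 1:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mu_eff(self) -> float:
        return effective_attenuation(self)

    @property
    def k0(self) -> float:
        """In-medium optical wavenumber in mm^-1."""
        return wavenumber_in_medium(self.wavelength_nm, self.n)


def effective_attenuation(props: OpticalProperties) -> float:
    """Effective attenuation coefficient ``sqrt(3 mu_a mu_s')`` in mm^-1.

    This is the diffusion-approximation decay constant of diffuse fluence
    with distance from the source.
    """
    return math.sqrt(3.0 * props.mu_a * props.mu_sp)


def scale_scattering_power_law(
    mu_sp_ref: float,
    lambda_ref_nm: float,
    lambda_target_nm: float,
    power: float = -1.5,
) -> float:
    """Scale a reduced scattering coefficient to another wavelength.

    Uses the standard power-law wavelength dependence
    ``mu_s'(lambda) = mu_s'(lambda_ref) * (lambda/lambda_ref)**power``
    with a default scattering power of -1.5 appropriate for adult forehead
    tissue.
    """
    if mu_sp_ref <= 0:
        raise ValueError(f"reference mu_s' must be positive, got {mu_sp_ref}")
    if lambda_ref_nm <= 0 or lambda_target_nm <= 0:
        raise ValueError("wavelengths must be positive")
    return mu_sp_ref * (lambda_target_nm / lambda_ref_nm) ** power


def extrapolation_lengths(props: OpticalProperties) -> tuple[float, float]:
    """Return ``(z0, zb)`` in mm for the extrapolated-boundary source image.

    ``z0 = 1/mu_s'`` is the depth of the isotropic point source equivalent to
    the pencil beam, and ``zb = 1.76/mu_s'`` the extrapolation length for a
    tissue refractive index of 1.37.
    """
    if props.mu_sp <= 0:  # defensive; dataclass already validates
        raise ValueError("mu_s' must be positive")
    z0 = 1.0 / props.mu_sp
    zb = ZB_FACTOR_N137 / props.mu_sp
    return z0, zb


def wavenumber_in_medium(wavelength_nm: float, n: float) -> float:
    """Optical wavenumber ``k0 = 2 pi n / lambda`` in mm^-1 (lambda in mm)."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    wavelength_mm = wavelength_nm * 1e-6
    return 2.0 * math.pi * n / wavelength_mm
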