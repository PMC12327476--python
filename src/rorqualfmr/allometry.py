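"""Allometric conversions: body length -> mass -> lung volumes.

Body mass is estimated from total length with a power law
``M_b = mass_a * TL**mass_b`` (kg from m), and total lung capacity from
mass with ``TLC = tlc_a * M_b**tlc_b`` (L from kg).  Vital capacity is a
fixed fraction of TLC (default 0.85).  Coefficient values are exposed in
the configuration so that species-specific literature values can be
swapped in without touching code; the defaults below are rounded
literature-style values suitable for the simulator and for worked
examples, not measurements of any particular population.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AllometricCoefficients:
    """Coefficients of the length->mass and mass->lung-volume power laws."""

    mass_a: float
    mass_b: float
    tlc_a: float = 0.135
    tlc_b: float = 0.92
    vc_fraction: float = 0.85
    source: str = ""

    def __post_init__(self) -> None:
        for name in ("mass_a", "mass_b", "tlc_a", "tlc_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.vc_fraction <= 1):
            raise ValueError("vc_fraction must be in (0, 1]")


#: Default species-keyed coefficients.  The mass laws are rounded rorqual
#: length-mass regressions; the lung law is the classical marine-mammal
#: TLC = 0.135 * M**0.92 relationship (L, kg).
DEFAULT_COEFFICIENTS: dict[str, AllometricCoefficients] = {
    "blue": AllometricCoefficients(
        mass_a=2.899, mass_b=3.25, source="rorqual length-mass regression (rounded)"
    ),
    "humpback": AllometricCoefficients(
        mass_a=15.5, mass_b=2.95, source="rorqual length-mass regression (rounded)"
    ),
    "minke": AllometricCoefficients(
        mass_a=12.0, mass_b=3.05, source="rorqual length-mass regression (rounded)"
    ),
}


@dataclass(frozen=True)
class MorphometricProfile:
    """Morphometric chain for one individual: TL -> M_b -> TLC -> VC."""

    species: str
    TL: float
    M_b: float
    TLC: float
    VC: float

    def __post_init__(self) -> None:
        for name in ("TL", "M_b", "TLC", "VC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def mass_from_length(TL: float, coeffs: AllometricCoefficients) -> float:
    """Body mass (kg) from total length (m): ``mass_a * TL**mass_b``."""
    if TL <= 0:
        raise ValueError(f"total length must be > 0, got {TL}")
    return coeffs.mass_a * TL**coeffs.mass_b


def tlc_from_mass(M_b: float, coeffs: AllometricCoefficients) -> float:
    """Total lung capacity (L) from body mass (kg): ``tlc_a * M_b**tlc_b``."""
    if M_b <= 0:
        raise ValueError(f"body mass must be > 0, got {M_b}")
    return coeffs.tlc_a * M_b**coeffs.tlc_b


def build_profile(
    species: str, TL: float, coeffs: AllometricCoefficients
) -> MorphometricProfile:
    """Chain TL -> mass -> TLC -> VC into a :class:`MorphometricProfile`.

    Vital capacity is ``vc_fraction`` (default 0.85) of total lung
    capacity, the usable portion of the lung in a maximal breath.
    """
    M_b = mass_from_length(TL, coeffs)
    TLC = tlc_from_mass(M_b, coeffs)
    VC = coeffs.vc_fraction * TLC
    return MorphometricProfile(species=species, TL=TL, M_b=M_b, TLC=TLC, VC=VC)
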