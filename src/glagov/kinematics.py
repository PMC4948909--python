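"""Geometry, growth law and the incompressible radial deformation map.

The artery is three concentric annuli with unstressed radii
``A < B < C < D`` (lumen, internal elastic lamina, media outer, adventitia
outer).  Only the intima grows, isotropically in-plane with growth stretch
``g(t) = exp(Gamma t / 2)``; incompressibility of the elastic response then
fixes the deformed radii ``b, c, d`` once the deformed lumen radius ``a`` is
known:

    b^2 = a^2 + g^2 (B^2 - A^2),   c^2 = b^2 + C^2 - B^2,
    d^2 = b^2 + D^2 - B^2.

Morphometric outputs follow histology conventions: lumen area ``pi a^2``,
IEL area ``pi b^2`` (area enclosed by the intima/media interface in the
deformed frame), plaque area their difference, stenosis plaque/IEL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReferenceGeometry",
    "GrowthState",
    "Configuration",
    "Morphometrics",
    "build_reference_geometry",
    "growth_factor",
    "time_from_growth",
    "radii_from_lumen",
    "deformation_map",
    "stretch_field",
    "morphometrics",
]

#: Reference-wall thickness defaults (mm): thin healthy intima, media and
#: adventitia from mechanical-testing literature.
DEFAULT_INTIMA_THICKNESS = 0.01
DEFAULT_MEDIA_THICKNESS = 0.32
DEFAULT_ADVENTITIA_THICKNESS = 0.34


@dataclass(frozen=True)
class ReferenceGeometry:
    """Unstressed radii of the three annuli, mm."""

    A: float
    B: float
    C: float
    D: float

    def __post_init__(self) -> None:
        if not (0.0 < self.A < self.B < self.C < self.D):
            raise ValueError(
                f"reference radii must satisfy 0 < A < B < C < D, got "
                f"A={self.A}, B={self.B}, C={self.C}, D={self.D}"
            )

    @property
    def lumen_area(self) -> float:
        return math.pi * self.A**2


@dataclass(frozen=True)
class GrowthState:
    """Isotropic intimal growth stretch ``g`` at time ``t`` under rate ``Gamma``."""

    g: float
    t: float  # years
    Gamma: float  # 1/year

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("time t must be non-negative")
        expected = math.exp(0.5 * self.Gamma * self.t)
        if not math.isclose(self.g, expected, rel_tol=1e-9):
            raise ValueError(
                f"inconsistent growth state: g={self.g} but exp(Gamma t / 2)={expected}"
            )

    @classmethod
    def at(cls, t: float, Gamma: float) -> "GrowthState":
        return cls(g=float(growth_factor(t, Gamma)), t=t, Gamma=Gamma)


@dataclass(frozen=True)
class Configuration:
    """A deformed mechanical state: radii at growth ``g`` and pressure ``P`` (kPa)."""

    a: float
    b: float
    c: float
    d: float
    g: float
    P: float  # kPa
    geometry: ReferenceGeometry

    def __post_init__(self) -> None:
        if not (0.0 < self.a < self.b < self.c < self.d):
            raise ValueError("deformed radii must satisfy 0 < a < b < c < d")


@dataclass(frozen=True)
class Morphometrics:
    """Histology-style cross-section metrics, mm^2 (stenosis a fraction)."""

    lumen_area: float
    iel_area: float
    plaque_area: float
    stenosis: float


def build_reference_geometry(
    reference_lumen_area: float,
    intima_thickness: float = DEFAULT_INTIMA_THICKNESS,
    media_thickness: float = DEFAULT_MEDIA_THICKNESS,
    adventitia_thickness: float = DEFAULT_ADVENTITIA_THICKNESS,
) -> ReferenceGeometry:
    """Reference geometry from an unstressed lumen area (mm^2) and layer thicknesses (mm)."""
    if reference_lumen_area <= 0:
        raise ValueError("reference_lumen_area must be positive")
    for name, t in (
        ("intima_thickness", intima_thickness),
        ("media_thickness", media_thickness),
        ("adventitia_thickness", adventitia_thickness),
    ):
        if t <= 0:
            raise ValueError(f"{name} must be positive")
    A = math.sqrt(reference_lumen_area / math.pi)
    B = A + intima_thickness
    C = B + media_thickness
    D = C + adventitia_thickness
    return ReferenceGeometry(A=A, B=B, C=C, D=D)


def growth_factor(t, Gamma: float):
    """Growth stretch ``g(t) = exp(Gamma t / 2)``.

    A constant volumetric production rate ``Gamma`` with equal radial and
    circumferential growth stretches gives ``trace(F_g^{-1} dF_g/dt) =
    2 g'/g = Gamma``, whose solution with ``g(0) = 1`` is the exponential.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be non-negative")
    if Gamma <= 0:
        raise ValueError("growth rate Gamma must be positive")
    out = np.exp(0.5 * Gamma * t)
    return out if out.ndim else float(out)


def time_from_growth(g, Gamma: float):
    """Inverse growth law: ``t = 2 ln(g) / Gamma`` (years)."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 1.0):
        raise ValueError("growth factor g must be >= 1")
    if Gamma <= 0:
        raise ValueError("growth rate Gamma must be positive")
    out = 2.0 * np.log(g) / Gamma
    return out if out.ndim else float(out)


def radii_from_lumen(a: float, g: float, geometry: ReferenceGeometry) -> tuple[float, float, float]:
    """Deformed interface radii ``(b, c, d)`` from the deformed lumen radius ``a``."""
    if a <= 0:
        raise ValueError("deformed lumen radius a must be positive")
    G = geometry
    b2 = a**2 + g**2 * (G.B**2 - G.A**2)
    b = math.sqrt(b2)
    c = math.sqrt(b2 + G.C**2 - G.B**2)
    d = math.sqrt(b2 + G.D**2 - G.B**2)
    return b, c, d


def deformation_map(R, a: float, g: float, geometry: ReferenceGeometry):
    """Deformed radius ``r(R)`` for reference radii ``R`` in ``[A, D]``."""
    G = geometry
    R = np.asarray(R, dtype=float)
    if np.any(R < G.A - 1e-12) or np.any(R > G.D + 1e-12):
        raise ValueError("reference radius R outside [A, D]")
    b2 = a**2 + g**2 * (G.B**2 - G.A**2)
    intima = R <= G.B
    r = np.where(
        intima,
        np.sqrt(a**2 + g**2 * (np.minimum(R, G.B) ** 2 - G.A**2)),
        np.sqrt(b2 + np.maximum(R, G.B) ** 2 - G.B**2),
    )
    return r if r.ndim else float(r)


def stretch_field(R, config: Configuration):
    """Circumferential elastic stretch ``alpha(R)`` of a configuration.

    In the grown intima ``alpha = r / (g R)``; in the media/adventitia
    ``alpha = r / R``.  Continuous across ``R = B``.
    """
    G = config.geometry
    R = np.asarray(R, dtype=float)
    if np.any(R < G.A - 1e-12) or np.any(R > G.D + 1e-12):
        raise ValueError("reference radius R outside [A, D]")
    r = deformation_map(R, config.a, config.g, G)
    alpha = np.where(np.asarray(R) <= G.B, np.asarray(r) / (config.g * R), np.asarray(r) / R)
    return alpha if alpha.ndim else float(alpha)


def morphometrics(config: Configuration) -> Morphometrics:
    """Lumen/IEL/plaque areas (mm^2) and stenosis fraction of a configuration."""
    lumen = math.pi * config.a**2
    iel = math.pi * config.b**2
    plaque = iel - lumen
    return Morphometrics(
        lumen_area=lumen,
        iel_area=iel,
        plaque_area=plaque,
        stenosis=plaque / iel,
    )
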