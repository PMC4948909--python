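"""Hyperelastic wall-layer models for a three-layer artery.

The intima is an incompressible Neo-Hookean solid; the media and adventitia
are fiber-reinforced (HGO/Fung-type) materials whose strain energy contains
an exponential term in combined isotropic and fiber invariants, modelling
collagen recruitment.  Because the vessel deforms as an incompressible
cylinder with unit axial stretch, every energy and stress here is a function
of the single circumferential elastic stretch ``alpha`` (the radial stretch
is ``1/alpha``).

Units: lengths mm, stresses/moduli kPa, angles degrees at the API surface
(converted to radians in exactly one place, :meth:`FiberReinforcedParams.phi_rad`).

The energy convention keeps the printed prefactors of the source model:
``omega_1 = mu_1 (alpha^2 + alpha^-2 - 2)`` with no factor 1/2.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "MMHG_TO_KPA",
    "DEFAULT_STRETCH_CAP",
    "StretchCapError",
    "NeoHookeanParams",
    "FiberReinforcedParams",
    "WallMaterials",
    "LayerParams",
    "fiber_terms",
    "energy_density",
    "reference_integrand",
    "deformed_integrand",
    "table1_materials",
    "load_materials",
]

#: 1 mmHg in kPa; luminal pressures are quoted in mmHg clinically but the
#: mechanics runs in kPa.
MMHG_TO_KPA = 0.1333224

#: Elastic stretches above this are rejected inside the fiber exponential:
#: with adventitial beta ~ 85 the term exp(beta*G) overflows long before, and
#: the physical model never strains the wall this far.  A violation therefore
#: signals a runaway trial state, not a meaningful configuration.
DEFAULT_STRETCH_CAP = 3.0


class StretchCapError(ValueError):
    """Raised when a fiber-layer stretch exceeds the diagnostic cap."""


def _check_alpha(alpha) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0.0):
        raise ValueError("circumferential stretch alpha must be positive")
    return alpha


@dataclass(frozen=True)
class NeoHookeanParams:
    """Neo-Hookean layer, energy ``mu (I1 - 3)`` with ``I1 = alpha^2 + alpha^-2 + 1``."""

    mu: float  # kPa

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


@dataclass(frozen=True)
class FiberReinforcedParams:
    """Fiber-reinforced exponential layer.

    Parameters
    ----------
    mu : float
        Ground-matrix shear-like modulus, kPa.
    eta : float
        Collagen stress scale, kPa.
    beta : float
        Dimensionless exponential stiffening rate.
    rho : float
        Weight in [0, 1] mixing the isotropic and fiber contributions inside
        the exponent.
    phi_deg : float
        Fiber angle from the circumferential direction, degrees in [0, 90].
    """

    mu: float
    eta: float
    beta: float
    rho: float
    phi_deg: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.eta < 0:
            raise ValueError(f"eta must be non-negative, got {self.eta}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if not 0.0 <= self.phi_deg <= 90.0:
            raise ValueError(f"phi_deg must lie in [0, 90], got {self.phi_deg}")

    @property
    def phi_rad(self) -> float:
        """Fiber angle in radians — the single degree→radian conversion point."""
        return math.radians(self.phi_deg)


LayerParams = Union[NeoHookeanParams, FiberReinforcedParams]


@dataclass(frozen=True)
class WallMaterials:
    """Constitutive parameters for the three concentric layers."""

    intima: NeoHookeanParams
    media: FiberReinforcedParams
    adventitia: FiberReinforcedParams

    def layers(self) -> tuple[LayerParams, LayerParams, LayerParams]:
        return (self.intima, self.media, self.adventitia)


def fiber_terms(alpha, params: FiberReinforcedParams):
    """Auxiliary fiber functions ``F(alpha)`` and ``G(alpha)`` of a fiber layer.

    With ``Q = alpha^2 + alpha^-2 - 2`` (isotropic over-stretch) and
    ``H = alpha^2 cos^2(phi) + sin^2(phi) - 1`` (fiber over-stretch),

    - ``F = (1 - rho) Q (1 - alpha^-4) + rho H cos^2(phi)``
    - ``G = (1 - rho) Q^2 + rho H^2``

    ``G >= 0`` always; both vanish at ``alpha = 1``.
    """
    alpha = _check_alpha(alpha)
    c2 = math.cos(params.phi_rad) ** 2
    s2 = math.sin(params.phi_rad) ** 2
    q = alpha**2 + alpha**-2 - 2.0
    h = alpha**2 * c2 + s2 - 1.0
    f = (1.0 - params.rho) * q * (1.0 - alpha**-4) + params.rho * h * c2
    g = (1.0 - params.rho) * q**2 + params.rho * h**2
    return f, g


def _check_cap(alpha: np.ndarray, stretch_cap: float) -> None:
    amax = float(np.max(alpha))
    if amax > stretch_cap:
        raise StretchCapError(
            f"stretch alpha={amax:.4g} exceeds the diagnostic cap {stretch_cap:.3g} "
            "in a fiber-layer exponential; the physical model never reaches such "
            "stretches — this usually indicates a runaway trial configuration"
        )


def energy_density(alpha, layer: LayerParams, stretch_cap: float = DEFAULT_STRETCH_CAP):
    """Strain-energy density ``omega(alpha)`` of a layer, kPa.

    Neo-Hookean: ``mu (alpha^2 + alpha^-2 - 2)``.
    Fiber-reinforced: ``mu (alpha^2 + alpha^-2 - 2) + (eta/beta)(exp(beta G) - 1)``.
    Non-negative, zero iff ``alpha == 1``.
    """
    alpha = _check_alpha(alpha)
    q = alpha**2 + alpha**-2 - 2.0
    if isinstance(layer, NeoHookeanParams):
        return layer.mu * q
    _check_cap(alpha, stretch_cap)
    _, g = fiber_terms(alpha, layer)
    return layer.mu * q + layer.eta / layer.beta * (np.exp(layer.beta * g) - 1.0)


def reference_integrand(alpha, layer: LayerParams, stretch_cap: float = DEFAULT_STRETCH_CAP):
    """Reference-frame radial-stress integrand (the factor on ``dR/R``), kPa.

    Neo-Hookean: ``2 mu (1 - alpha^-4)``.
    Fiber-reinforced: ``2 mu (1 - alpha^-4) + 4 eta F exp(beta G)``.
    """
    alpha = _check_alpha(alpha)
    iso = 2.0 * layer.mu * (1.0 - alpha**-4)
    if isinstance(layer, NeoHookeanParams):
        return iso
    _check_cap(alpha, stretch_cap)
    f, g = fiber_terms(alpha, layer)
    return iso + 4.0 * layer.eta * f * np.exp(layer.beta * g)


def deformed_integrand(alpha, layer: LayerParams, stretch_cap: float = DEFAULT_STRETCH_CAP):
    """Deformed-frame radial-stress integrand (the factor on ``dr/r``), kPa.

    Equals ``alpha^2`` times :func:`reference_integrand` — the change of frame
    uses ``dr/r = (1/alpha^2) dR/R``.  Also equals ``alpha * d(omega)/d(alpha)``,
    so the hoop-radial stress difference ``T_thetatheta - T_rr`` is this value.
    """
    alpha = _check_alpha(alpha)
    return alpha**2 * reference_integrand(alpha, layer, stretch_cap=stretch_cap)


#: Literature/estimated parameter set for a human coronary artery (moduli kPa,
#: angles degrees): intima mu 5; media (mu 1.27, eta 21.60, beta 8.21,
#: phi 20.61 deg, rho 0.25); adventitia (mu 7.56, eta 38.57, beta 85.03,
#: phi 67.0 deg, rho 0.55).
_DEFAULTS = {
    "mu1": 5.0,
    "mu2": 1.27,
    "eta2": 21.60,
    "beta2": 8.21,
    "phi2_deg": 20.61,
    "rho2": 0.25,
    "mu3": 7.56,
    "eta3": 38.57,
    "beta3": 85.03,
    "phi3_deg": 67.0,
    "rho3": 0.55,
}


def _materials_from_mapping(cfg: dict) -> WallMaterials:
    unknown = set(cfg) - set(_DEFAULTS)
    if unknown:
        raise KeyError(f"unknown material keys: {sorted(unknown)}")
    v = {**_DEFAULTS, **cfg}
    return WallMaterials(
        intima=NeoHookeanParams(mu=v["mu1"]),
        media=FiberReinforcedParams(
            mu=v["mu2"], eta=v["eta2"], beta=v["beta2"], rho=v["rho2"], phi_deg=v["phi2_deg"]
        ),
        adventitia=FiberReinforcedParams(
            mu=v["mu3"], eta=v["eta3"], beta=v["beta3"], rho=v["rho3"], phi_deg=v["phi3_deg"]
        ),
    )


def table1_materials() -> WallMaterials:
    """The default coronary-artery parameter set (see ``_DEFAULTS``)."""
    return _materials_from_mapping({})


def load_materials(path: str | Path) -> WallMaterials:
    """Read wall materials from a TOML file.

    Keys (all optional, defaults above): ``mu1, mu2, eta2, beta2, phi2_deg,
    rho2, mu3, eta3, beta3, phi3_deg, rho3``, either at top level or under a
    ``[materials]`` table.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cfg = data.get("materials", data)
    return _materials_from_mapping(cfg)
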