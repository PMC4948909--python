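"""Growth trajectories, Glagov curves and critical-stenosis detection.

Drives the equilibrium solve over a growth schedule, producing the
remodeling curve ``L = f(S)`` (lumen area against stenosis fraction) for one
vessel.  Ex-vivo (``P = 0``) curves are non-monotone for the default
coronary parameters — compensatory outward remodeling followed by luminal
encroachment — and the interior maximum defines the critical stenosis
``S*`` (``f'(S*) = 0``, ``f''(S*) < 0``).  In-vivo (pressurized) curves are
monotone decreasing and have no critical stenosis.

Because the growth law is stress-independent, the curve plotted against
stenosis is invariant to the growth rate ``Gamma``; ``Gamma`` only sets the
clock on the time axis of trajectory exports.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .constitutive import MMHG_TO_KPA, StretchCapError, WallMaterials
from .equilibrium import EquilibriumError, SolverSettings, solve_configuration
from .kinematics import (
    Configuration,
    ReferenceGeometry,
    morphometrics,
    time_from_growth,
)

__all__ = [
    "RemodelingCurve",
    "CriticalStenosis",
    "ExVivoInVivoComparison",
    "simulate_remodeling",
    "growth_for_stenosis",
    "critical_stenosis",
    "compensation_slope",
    "exvivo_invivo_table",
]

#: Trajectories stop before total occlusion; the model is not trusted there.
DEFAULT_S_MAX = 0.9
DEFAULT_N_STEPS = 400


@dataclass(frozen=True)
class RemodelingCurve:
    """Metrics of one vessel along a growth schedule (arrays share length)."""

    g: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    stenosis: np.ndarray
    lumen_area: np.ndarray
    iel_area: np.ndarray
    plaque_area: np.ndarray
    P_mmHg: float
    Gamma: float
    geometry: ReferenceGeometry

    def __len__(self) -> int:
        return len(self.g)

    @property
    def t_years(self) -> np.ndarray:
        return time_from_growth(self.g, self.Gamma)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_years": self.t_years,
                "g": self.g,
                "P_mmHg": np.full_like(self.g, self.P_mmHg),
                "a_mm": self.a,
                "b_mm": self.b,
                "c_mm": self.c,
                "d_mm": self.d,
                "lumen_area_mm2": self.lumen_area,
                "iel_area_mm2": self.iel_area,
                "plaque_area_mm2": self.plaque_area,
                "stenosis_fraction": self.stenosis,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CriticalStenosis:
    """Interior maximum of ``L = f(S)``; ``S_star is None`` when the curve is monotone."""

    S_star: float | None
    L_at_S_star: float | None

    @property
    def present(self) -> bool:
        return self.S_star is not None


def growth_for_stenosis(
    S_target: float,
    P_mmHg: float,
    geometry: ReferenceGeometry,
    materials: WallMaterials,
    settings: SolverSettings | None = None,
    tol: float = 1e-4,
) -> float:
    """Growth factor at which the (solved) stenosis reaches ``S_target``.

    Stenosis increases with ``g`` along a trajectory, so a doubling search
    followed by bisection suffices.
    """
    if not 0.0 < S_target < 1.0:
        raise ValueError("S_target must lie in (0, 1)")
    P = P_mmHg * MMHG_TO_KPA

    def stenosis_at(g: float) -> float | None:
        # Far past the target the collagen exponentials leave no physically
        # meaningful equilibrium; treat a failed solve as "beyond the target"
        # (stenosis is monotone in g) so the search backs off.  Fresh starts
        # on purpose: a warm start from across a large growth jump can
        # mislead the bracketer.
        try:
            cfg = solve_configuration(g, P, geometry, materials, settings)
        except (EquilibriumError, StretchCapError):
            return None
        return morphometrics(cfg).stenosis

    lo, hi = 1.0, 2.0
    s = stenosis_at(hi)
    while s is not None and s < S_target:
        lo, hi = hi, hi * 2.0
        if hi > 1e3:
            raise RuntimeError("stenosis target not reached at any plausible growth")
        s = stenosis_at(hi)
    while hi - lo > tol * lo:
        mid = math.sqrt(lo * hi)
        s = stenosis_at(mid)
        if s is not None and s < S_target:
            lo = mid
        else:
            hi = mid
    return lo


def simulate_remodeling(
    geometry: ReferenceGeometry,
    materials: WallMaterials,
    P_mmHg: float = 0.0,
    Gamma: float = 0.5,
    g_max: float | None = None,
    S_max: float = DEFAULT_S_MAX,
    n_steps: int = DEFAULT_N_STEPS,
    settings: SolverSettings | None = None,
) -> RemodelingCurve:
    """Quasi-static remodeling trajectory at constant luminal pressure.

    The growth grid is geometric in ``g`` (uniform in time) with ``n_steps``
    points from 1 to ``g_max``; when ``g_max`` is omitted it is chosen so the
    final stenosis reaches ``S_max``.  Each grid point is an independent
    equilibrium solve warm-started from its predecessor.
    """
    if P_mmHg < 0:
        raise ValueError("pressure must be non-negative")
    if n_steps < 2:
        raise ValueError("need at least 2 growth steps")
    if g_max is None:
        g_max = growth_for_stenosis(S_max, P_mmHg, geometry, materials, settings)
    if g_max <= 1.0:
        raise ValueError("g_max must exceed 1")
    P = P_mmHg * MMHG_TO_KPA
    gs = np.geomspace(1.0, g_max, n_steps)

    rows = np.empty((n_steps, 8))
    guess = None
    for i, g in enumerate(gs):
        cfg = solve_configuration(g, P, geometry, materials, settings, initial_guess=guess)
        guess = cfg.a
        m = morphometrics(cfg)
        rows[i] = (cfg.a, cfg.b, cfg.c, cfg.d, m.stenosis, m.lumen_area, m.iel_area, m.plaque_area)

    return RemodelingCurve(
        g=gs,
        a=rows[:, 0],
        b=rows[:, 1],
        c=rows[:, 2],
        d=rows[:, 3],
        stenosis=rows[:, 4],
        lumen_area=rows[:, 5],
        iel_area=rows[:, 6],
        plaque_area=rows[:, 7],
        P_mmHg=P_mmHg,
        Gamma=Gamma,
        geometry=geometry,
    )


def _curve_arrays(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, RemodelingCurve):
        return curve.stenosis, curve.lumen_area
    S, L = curve
    return np.asarray(S, dtype=float), np.asarray(L, dtype=float)


#: An interior maximum must sit at least this many grid points from either
#: curve end to be trusted (avoids boundary artifacts of the interpolant).
_EDGE_GUARD = 2


def critical_stenosis(curve) -> CriticalStenosis:
    """Locate the critical stenosis of a remodeling curve, if any.

    Accepts a :class:`RemodelingCurve` or an ``(S, L)`` pair of arrays.  The
    interior maximum of a cubic-spline interpolant of ``L(S)`` is refined by
    bounded golden-section search between the neighbours of the discrete
    argmax (a shape-preserving interpolant would pin the maximum to a grid
    point and bias the location by up to half a grid step); a maximum on (or
    hugging) the boundary means the curve is monotone there and yields
    ``S_star = None``.
    """
    S, L = _curve_arrays(curve)
    if len(S) < 10:
        raise ValueError("need at least 10 samples to locate a critical stenosis")
    order = np.argsort(S)
    S, L = S[order], L[order]

    i = int(np.argmax(L))
    if i < _EDGE_GUARD or i >= len(S) - _EDGE_GUARD:
        return CriticalStenosis(S_star=None, L_at_S_star=None)

    f = CubicSpline(S, L, bc_type="natural")
    res = minimize_scalar(
        lambda s: -f(s), bounds=(S[i - 1], S[i + 1]), method="bounded",
        options={"xatol": 1e-10},
    )
    s_star = float(res.x)
    # Numerical curvature check: a genuine interior maximum is concave.
    h = max(1e-6, 1e-4 * (S[-1] - S[0]))
    curv = (f(s_star - h) - 2.0 * f(s_star) + f(s_star + h)) / h**2
    if curv >= 0:
        warnings.warn(
            "located maximum fails the concavity check; treating as absent",
            RuntimeWarning,
            stacklevel=2,
        )
        return CriticalStenosis(S_star=None, L_at_S_star=None)
    return CriticalStenosis(S_star=s_star, L_at_S_star=float(f(s_star)))


def compensation_slope(
    curve,
    plaque_area_window: float = 0.5,
    stenosis_window: float | None = None,
) -> float:
    """Early-stage slope of lumen area against plaque area (mm^2 per mm^2).

    Least-squares slope restricted to ``plaque_area <= plaque_area_window``
    (default 0.5 mm^2), or — mirroring the histology convention of analysing
    only mildly stenotic sections — to ``stenosis <= stenosis_window`` when
    that is given instead.  Positive slope means early over-compensation:
    the lumen gains area while plaque accumulates.
    """
    if not isinstance(curve, RemodelingCurve):
        raise TypeError("compensation_slope needs a RemodelingCurve")
    if stenosis_window is not None:
        mask = curve.stenosis <= stenosis_window
    else:
        mask = curve.plaque_area <= plaque_area_window
    if mask.sum() < 2:
        raise ValueError("window selects fewer than 2 early-stage points")
    slope = np.polyfit(curve.plaque_area[mask], curve.lumen_area[mask], 1)[0]
    return float(slope)


@dataclass(frozen=True)
class ExVivoInVivoComparison:
    """Same vessel, same growth, solved unpressurized and pressurized."""

    g: float
    P_invivo_mmHg: float
    exvivo: Configuration
    invivo: Configuration

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name, cfg in (("ex_vivo", self.exvivo), ("in_vivo", self.invivo)):
            m = morphometrics(cfg)
            rows[name] = {
                "iel_area_mm2": m.iel_area,
                "lumen_area_mm2": m.lumen_area,
                "plaque_area_mm2": m.plaque_area,
                "stenosis_fraction": m.stenosis,
            }
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        buf = io.StringIO()
        buf.write(f"g = {self.g:g}, in-vivo pressure = {self.P_invivo_mmHg:g} mmHg\n")
        buf.write(df.to_string(float_format=lambda x: f"{x:.6g}"))
        ex, iv = df["ex_vivo"], df["in_vivo"]
        buf.write("\n\nex-vivo vs in-vivo: ")
        buf.write(
            f"IEL {'smaller' if ex.iel_area_mm2 < iv.iel_area_mm2 else 'larger'}, "
            f"lumen {'smaller' if ex.lumen_area_mm2 < iv.lumen_area_mm2 else 'larger'}, "
            f"plaque same, "
            f"stenosis {'larger' if ex.stenosis_fraction > iv.stenosis_fraction else 'smaller'}"
        )
        return buf.getvalue()


def exvivo_invivo_table(
    g: float,
    geometry: ReferenceGeometry,
    materials: WallMaterials,
    P_invivo_mmHg: float = 80.0,
    settings: SolverSettings | None = None,
) -> ExVivoInVivoComparison:
    """Solve the same grown vessel with and without luminal pressure.

    Depressurizing shrinks both the IEL and the lumen; plaque area is
    pressure-invariant (incompressibility), so the measured stenosis is
    larger ex-vivo.
    """
    if g < 1.0:
        raise ValueError("growth factor g must be >= 1")
    ex = solve_configuration(g, 0.0, geometry, materials, settings)
    iv = solve_configuration(g, P_invivo_mmHg * MMHG_TO_KPA, geometry, materials, settings)
    return ExVivoInVivoComparison(g=g, P_invivo_mmHg=P_invivo_mmHg, exvivo=ex, invivo=iv)
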