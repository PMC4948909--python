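"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from the displayed formulas with its
own literal parameter constants and brute-force numerics (dense trapezoid
quadrature, bisection, exact quadratic minimization) so it shares no code
path with the package under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import CubicSpline

# Coronary three-layer parameter set, transcribed independently.
MU1 = 5.0
MU2, ETA2, BETA2, PHI2, RHO2 = 1.27, 21.60, 8.21, math.radians(20.61), 0.25
MU3, ETA3, BETA3, PHI3, RHO3 = 7.56, 38.57, 85.03, math.radians(67.0), 0.55
T_INTIMA, T_MEDIA, T_ADVENTITIA = 0.01, 0.32, 0.34
MMHG = 0.1333224


def fiber_FG(alpha, phi, rho):
    q = alpha**2 + alpha**-2 - 2.0
    h = alpha**2 * math.cos(phi) ** 2 + math.sin(phi) ** 2 - 1.0
    F = (1.0 - rho) * q * (1.0 - alpha**-4) + rho * h * math.cos(phi) ** 2
    G = (1.0 - rho) * q**2 + rho * h**2
    return F, G


def omega_fiber(alpha, mu, eta, beta, phi, rho):
    q = alpha**2 + alpha**-2 - 2.0
    _, G = fiber_FG(alpha, phi, rho)
    return mu * q + eta / beta * (math.exp(beta * G) - 1.0)


def ref_integrand(alpha, layer: int):
    """Reference-frame integrand; layer 1=intima, 2=media, 3=adventitia."""
    if layer == 1:
        return 2.0 * MU1 * (1.0 - alpha**-4)
    mu, eta, beta, phi, rho = (
        (MU2, ETA2, BETA2, PHI2, RHO2) if layer == 2 else (MU3, ETA3, BETA3, PHI3, RHO3)
    )
    F, G = np.vectorize(lambda a: fiber_FG(a, phi, rho))(alpha)
    return 2.0 * mu * (1.0 - np.asarray(alpha) ** -4.0) + 4.0 * eta * F * np.exp(beta * G)


def trapezoid_residual(a, g, P_kPa, A, n=10_000):
    """Force balance by dense fixed-grid trapezoid quadrature (test-only oracle)."""
    B = A + T_INTIMA
    C = B + T_MEDIA
    D = C + T_ADVENTITIA
    total = -P_kPa
    R = np.linspace(A, B, n)
    alpha = np.sqrt(a**2 + g**2 * (R**2 - A**2)) / (g * R)
    total += np.trapezoid(ref_integrand(alpha, 1) / R, R)
    b2 = a**2 + g**2 * (B**2 - A**2)
    for lo, hi, layer in ((B, C, 2), (C, D, 3)):
        R = np.linspace(lo, hi, n)
        alpha = np.sqrt(b2 + R**2 - B**2) / R
        total += np.trapezoid(ref_integrand(alpha, layer) / R, R)
    return total


def bisect_equilibrium(g, P_kPa, A, lo_fac=0.02, hi_fac=2.0, tol=1e-10):
    """Lumen radius by bisection on the trapezoid residual."""
    lo, hi = lo_fac * g * A, hi_fac * g * A
    with np.errstate(over="ignore"):
        flo = trapezoid_residual(lo, g, P_kPa, A)
        fhi = trapezoid_residual(hi, g, P_kPa, A)
        assert flo < 0 < fhi, (flo, fhi)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if trapezoid_residual(mid, g, P_kPa, A) < 0:
                lo = mid
            else:
                hi = mid
    return 0.5 * (lo + hi)


def natural_spline_objective(x, y, f, k):
    """Penalized objective of the natural cubic spline through (x, f).

    The curvature of a cubic spline is piecewise linear, so the penalty
    integral is summed exactly per interval.
    """
    cs = CubicSpline(x, f, bc_type="natural")
    misfit = float(np.sum((np.asarray(y) - np.asarray(f)) ** 2))
    u = cs(x, 2)
    h = np.diff(x)
    penalty = float(np.sum(h / 3.0 * (u[:-1] ** 2 + u[:-1] * u[1:] + u[1:] ** 2)))
    return k * misfit + (1.0 - k) * penalty


def minimize_spline_objective(x, y, k):
    """Exact minimizer of the (quadratic) objective over knot values.

    The objective is quadratic in the knot values f, so its gradient and
    Hessian assembled by symmetric finite differences are exact; the
    stationary point is one linear solve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)

    def obj(f):
        return natural_spline_objective(x, y, f, k)

    c0 = obj(np.zeros(n))
    E = np.eye(n)
    grad = np.empty(n)
    H = np.empty((n, n))
    plus = np.array([obj(E[i]) for i in range(n)])
    minus = np.array([obj(-E[i]) for i in range(n)])
    grad = (plus - minus) / 2.0
    np.fill_diagonal(H, plus + minus - 2.0 * c0)
    for i in range(n):
        for j in range(i + 1, n):
            oij = obj(E[i] + E[j])
            H[i, j] = H[j, i] = oij - c0 - grad[i] - grad[j] - 0.5 * (H[i, i] + H[j, j])
    f_star = np.linalg.solve(H, -grad)
    return f_star, obj(f_star)
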