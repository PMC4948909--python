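"""Penalized cubic smoothing splines for (stenosis, lumen-area) data.

For samples ``(s_i, l_i)`` the fit minimizes

    k * sum_i (l_i - L(s_i))^2  +  (1 - k) * int (L''(S))^2 dS,

over natural cubic splines ``L`` with knots at the data sites, the integral
running over the span of the ``s_i``.  The weighting is exactly ``(k, 1-k)``
with ``k`` in [0, 1]: ``k -> 0`` recovers the least-squares straight line,
``k -> 1`` the natural interpolating spline.  The minimizer solves the
Reinsch banded system (Green & Silverman form): with second-derivative
vector ``gamma`` at interior knots and ``lambda = (1-k)/k``,

    (R + lambda Q^T W^{-1} Q) gamma = Q^T y,      f = y - lambda W^{-1} Q gamma,

where ``Q``/``R`` are the usual tridiagonal difference/overlap matrices and
``W`` holds multiplicities of aggregated duplicate sites.

Alongside the functional API, :class:`SmoothingSpline` exposes the fit as a
scikit-learn regressor so it composes with pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.linalg import solveh_banded
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "RemodelingSample",
    "SplineFit",
    "SmoothingSpline",
    "fit_smoothing_spline",
    "interior_maximum",
    "k_sweep",
]


class RemodelingSample(NamedTuple):
    """One observed cross-section: stenosis fraction and lumen area (mm^2)."""

    s: float
    l: float


def _as_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, pd.DataFrame):
        s = samples["stenosis_fraction"].to_numpy(dtype=float)
        l = samples["lumen_area_mm2"].to_numpy(dtype=float)
    elif isinstance(samples, tuple) and len(samples) == 2 and np.ndim(samples[0]) == 1:
        s = np.asarray(samples[0], dtype=float)
        l = np.asarray(samples[1], dtype=float)
    else:
        arr = np.asarray(list(samples), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("samples must be (s, l) pairs")
        s, l = arr[:, 0], arr[:, 1]
    if np.any(s < 0) or np.any(s >= 1):
        raise ValueError("stenosis values must lie in [0, 1)")
    if np.any(l <= 0):
        raise ValueError("lumen areas must be positive")
    return s, l


def _aggregate_duplicates(s, l) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse repeated stenosis sites to their mean, weighting by count."""
    x, inverse, counts = np.unique(s, return_inverse=True, return_counts=True)
    if len(x) == len(s):
        order = np.argsort(s)
        return s[order], l[order], np.ones(len(s))
    warnings.warn(
        f"{len(s) - len(x)} duplicate stenosis value(s) aggregated by averaging",
        UserWarning,
        stacklevel=3,
    )
    y = np.bincount(inverse, weights=l) / counts
    return x, y, counts.astype(float)


def _reinsch_matrices(x: np.ndarray):
    """Q (n x n-2) and the tridiagonal R (n-2 x n-2) for knots x."""
    n = len(x)
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    for j in range(n - 2):
        i = j + 1  # interior knot index
        Q[i - 1, j] = 1.0 / h[i - 1]
        Q[i, j] = -1.0 / h[i - 1] - 1.0 / h[i]
        Q[i + 1, j] = 1.0 / h[i]
    R = np.zeros((n - 2, n - 2))
    for j in range(n - 2):
        i = j + 1
        R[j, j] = (h[i - 1] + h[i]) / 3.0
        if j + 1 < n - 2:
            R[j, j + 1] = R[j + 1, j] = h[i] / 6.0
    return Q, R


def _penalty(gamma: np.ndarray, R: np.ndarray) -> float:
    """int (L'')^2 over the knot span, = gamma^T R gamma."""
    return float(gamma @ R @ gamma)


def _solve_reinsch(x, y, w, k) -> tuple[np.ndarray, float]:
    """Fitted values at the knots and the curvature penalty, for k in (0, 1]."""
    Q, R = _reinsch_matrices(x)
    qty = Q.T @ y
    if k == 1.0:
        f = y.copy()
        gamma = np.linalg.solve(R, qty)  # natural interpolant curvature
        return f, _penalty(gamma, R)
    lam = (1.0 - k) / k
    M = R + lam * (Q.T @ (Q / w[:, None]))
    m = M.shape[0]
    # Symmetric banded (bandwidth 2) storage for a Cholesky band solve.
    ab = np.zeros((3, m))
    ab[2] = np.diag(M)
    if m > 1:
        ab[1, 1:] = np.diag(M, 1)
    if m > 2:
        ab[0, 2:] = np.diag(M, 2)
    gamma = solveh_banded(ab, qty)
    f = y - lam * (Q @ gamma) / w
    return f, _penalty(gamma, R)


@dataclass(frozen=True)
class SplineFit:
    """A fitted penalized natural cubic smoothing spline L(S)."""

    knots: np.ndarray
    values: np.ndarray  # fitted L at the knots
    weights: np.ndarray  # duplicate multiplicities
    k: float
    misfit: float  # sum_i w_i (l_i - L(s_i))^2
    penalty: float  # int (L'')^2 dS
    spline: CubicSpline = field(repr=False)

    @property
    def objective(self) -> float:
        return self.k * self.misfit + (1.0 - self.k) * self.penalty

    @property
    def coefficients(self) -> np.ndarray:
        """Piecewise-polynomial coefficients of the natural cubic spline."""
        return self.spline.c

    def __call__(self, s):
        return self.spline(s)


def fit_smoothing_spline(samples, k: float) -> SplineFit:
    """Fit the penalized smoothing spline with trade-off parameter ``k``.

    Requires at least 4 distinct stenosis sites; duplicate sites are
    averaged (with a warning) and weighted by multiplicity so the original
    objective is preserved.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"smoothing parameter k must lie in [0, 1], got {k}")
    s, l = _as_arrays(samples)
    x, y, w = _aggregate_duplicates(s, l)
    if len(x) < 4:
        raise ValueError("need at least 4 distinct stenosis values")

    if k == 0.0:
        coef = np.polyfit(x, y, 1, w=np.sqrt(w))
        f = np.polyval(coef, x)
        penalty = 0.0
    else:
        f, penalty = _solve_reinsch(x, y, w, k)

    # The minimizer over natural cubic splines is the natural interpolant of
    # its own knot values, so the functional form follows from f alone.
    spline = CubicSpline(x, f, bc_type="natural")
    misfit = float(w @ (y - f) ** 2)
    return SplineFit(
        knots=x, values=f, weights=w, k=k, misfit=misfit, penalty=penalty, spline=spline
    )


def interior_maximum(fit: SplineFit) -> float | None:
    """Stenosis of the largest local maximum strictly inside the data span.

    Candidate locations are the analytic roots of the spline's first
    derivative; a candidate counts as a local maximum when the derivative
    changes sign from positive to negative.  Returns ``None`` when the fit
    is monotone over the span.
    """
    x0, x1 = fit.knots[0], fit.knots[-1]
    d = fit.spline.derivative()
    with np.errstate(invalid="ignore"):
        roots = np.atleast_1d(d.roots(extrapolate=False))
    roots = roots[np.isfinite(roots)]
    eps = 1e-9 * (x1 - x0)
    roots = roots[(roots > x0 + eps) & (roots < x1 - eps)]
    maxima = [
        float(r)
        for r in np.unique(roots)
        if d(max(x0, r - eps * 10)) > 0 > d(min(x1, r + eps * 10))
    ]
    if not maxima:
        return None
    vals = fit.spline(maxima)
    return float(maxima[int(np.argmax(vals))])


def k_sweep(samples, k_grid) -> pd.DataFrame:
    """One smoothing-spline fit per ``k``, tracking interior-maximum emergence.

    Returns a frame with columns ``k, S_max, L_at_max, misfit, penalty,
    objective`` (``S_max`` is NaN where the fit is monotone).  Along the
    sweep the misfit term is non-increasing and the penalty non-decreasing
    in ``k``.
    """
    rows = []
    for k in np.asarray(list(k_grid), dtype=float):
        fit = fit_smoothing_spline(samples, float(k))
        s_max = interior_maximum(fit)
        rows.append(
            {
                "k": float(k),
                "S_max": np.nan if s_max is None else s_max,
                "L_at_max": np.nan if s_max is None else float(fit(s_max)),
                "misfit": fit.misfit,
                "penalty": fit.penalty,
                "objective": fit.objective,
            }
        )
    return pd.DataFrame(rows)


class SmoothingSpline(RegressorMixin, BaseEstimator):
    """Scikit-learn regressor wrapping :func:`fit_smoothing_spline`.

    Parameters
    ----------
    k : float, default 0.5
        Trade-off in [0, 1] between data fidelity (k -> 1, interpolation)
        and curvature penalty (k -> 0, straight line).
    """

    def __init__(self, k: float = 0.5):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("SmoothingSpline expects a single feature (stenosis)")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y have inconsistent lengths")
        fit = fit_smoothing_spline((X, y), self.k)
        self.fit_ = fit
        self.knots_ = fit.knots
        self.values_ = fit.values
        self.misfit_ = fit.misfit
        self.penalty_ = fit.penalty
        self.objective_ = fit.objective
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "fit_"):
            raise AttributeError("SmoothingSpline is not fitted yet")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.fit_.spline(X)

    def interior_maximum(self) -> float | None:
        if not hasattr(self, "fit_"):
            raise AttributeError("SmoothingSpline is not fitted yet")
        return interior_maximum(self.fit_)
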