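"""Synthetic cross-sectional cohorts of remodeling vessels.

Emulates the statistical structure of histology / imaging point clouds of
(stenosis, lumen area) pairs: each vessel gets its own reference lumen
area, growth rate and observation time, is simulated to equilibrium at
that time, and is observed with additive Gaussian noise on the lumen area.
Ex-vivo cohorts are unpressurized; in-vivo cohorts draw a physiological
pressure per vessel and — mirroring older clinical cohorts that contain
essentially no early plaques — can discard sections below a minimum
stenosis.

All randomness flows from a single seeded generator, so a cohort is fully
reproducible from its spec.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constitutive import MMHG_TO_KPA, StretchCapError, WallMaterials, table1_materials
from .equilibrium import EquilibriumError, SolverSettings, solve_configuration
from .kinematics import build_reference_geometry, morphometrics

__all__ = ["CohortSpec", "generate_cohort", "write_fixture", "read_fixture"]

SAMPLE_COLUMNS = ["stenosis_fraction", "lumen_area_mm2"]


@dataclass(frozen=True)
class CohortSpec:
    """Population and observation model for one synthetic cohort.

    Defaults describe an ex-vivo, histology-like cohort: reference lumen
    areas uniform over 5–15 mm^2, growth rate log-normal with median
    0.5/year, observation times uniform over 0–10 years (stenoses then span
    roughly 0.05–0.85; draws landing above ``max_stenosis`` are re-timed),
    and 1 mm^2 measurement noise on lumen area.
    """

    n_vessels: int = 150
    area_range: tuple[float, float] = (5.0, 15.0)  # mm^2, uniform
    gamma_median: float = 0.5  # 1/year, log-normal median
    gamma_log_sd: float = 0.35  # dimensionless sd of ln(Gamma)
    time_max_years: float = 10.0  # observation time uniform over [0, T]
    sigma_L: float = 1.0  # mm^2, Gaussian noise on lumen area
    pressure_mode: str = "exvivo"  # "exvivo" (P=0) or "invivo" (P uniform)
    pressure_range_mmHg: tuple[float, float] = (50.0, 110.0)
    min_stenosis: float = 0.0  # sections below this are re-timed (in-vivo preset: 0.10)
    max_stenosis: float = 0.85  # beyond model trust; re-timed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels <= 0:
            raise ValueError("n_vessels must be positive")
        if self.sigma_L < 0:
            raise ValueError("sigma_L must be non-negative")
        if self.pressure_mode not in ("exvivo", "invivo"):
            raise ValueError("pressure_mode must be 'exvivo' or 'invivo'")
        if not 0.0 <= self.min_stenosis < self.max_stenosis < 1.0:
            raise ValueError("need 0 <= min_stenosis < max_stenosis < 1")


def invivo_spec(**overrides) -> CohortSpec:
    """In-vivo preset: pressurized vessels, no early (<10% stenosis) sections."""
    return replace(CohortSpec(pressure_mode="invivo", min_stenosis=0.10), **overrides)


def generate_cohort(
    spec: CohortSpec,
    materials: WallMaterials | None = None,
    settings: SolverSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw and simulate one cohort.

    Returns
    -------
    samples : DataFrame
        Observed ``stenosis_fraction, lumen_area_mm2`` (noisy), one row per
        vessel.
    truth : DataFrame
        Per-vessel ground truth: drawn parameters and the noiseless
        ``stenosis_true, lumen_true_mm2`` on the model curve.
    """
    materials = materials or table1_materials()
    rng = np.random.default_rng(spec.seed)
    mu_ln = math.log(spec.gamma_median)

    samples, truth = [], []
    for vessel in range(spec.n_vessels):
        area0 = rng.uniform(*spec.area_range)
        geom = build_reference_geometry(area0)

        # Re-draw the observation time until the section is inside the
        # observable stenosis window (stenosis is monotone in time).  A
        # slowly growing vessel may be unable to reach the window's floor
        # within the observation horizon; after exhausting re-times its
        # growth rate (and pressure) are re-drawn.
        placed = False
        for _ in range(40):
            gamma = float(np.exp(rng.normal(mu_ln, spec.gamma_log_sd)))
            if spec.pressure_mode == "invivo":
                P_mmHg = rng.uniform(*spec.pressure_range_mmHg)
            else:
                P_mmHg = 0.0
            P = P_mmHg * MMHG_TO_KPA
            for _ in range(25):
                t = rng.uniform(0.0, spec.time_max_years)
                g = math.exp(0.5 * gamma * t)
                try:
                    cfg = solve_configuration(g, P, geom, materials, settings)
                except (EquilibriumError, StretchCapError):
                    continue  # runaway growth draw; re-time
                m = morphometrics(cfg)
                if spec.min_stenosis <= m.stenosis <= spec.max_stenosis:
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise RuntimeError(f"could not place vessel {vessel} in the stenosis window")

        l_obs = m.lumen_area + rng.normal(0.0, spec.sigma_L)
        while l_obs <= 0:  # lumen areas are physical; resample the rare bad draw
            l_obs = m.lumen_area + rng.normal(0.0, spec.sigma_L)
        samples.append({"stenosis_fraction": m.stenosis, "lumen_area_mm2": l_obs})
        truth.append(
            {
                "vessel": vessel,
                "area0_mm2": area0,
                "Gamma": gamma,
                "t_years": t,
                "g": g,
                "P_mmHg": P_mmHg,
                "stenosis_true": m.stenosis,
                "lumen_true_mm2": m.lumen_area,
            }
        )
    return pd.DataFrame(samples, columns=SAMPLE_COLUMNS), pd.DataFrame(truth)


def write_fixture(samples, path) -> None:
    """Write samples as CSV with the two-column schema (lossless round-trip)."""
    if isinstance(samples, pd.DataFrame):
        df = samples[SAMPLE_COLUMNS]
    else:
        df = pd.DataFrame(list(samples), columns=SAMPLE_COLUMNS)
    df.to_csv(path, index=False)


def read_fixture(path) -> pd.DataFrame:
    """Read a (stenosis, lumen-area) CSV.

    Requires columns ``stenosis_fraction`` and ``lumen_area_mm2`` (extra
    columns are ignored).  Percent-coded stenosis (values above 1.5) is
    auto-detected and converted to fractions with a warning.  Malformed
    numeric fields raise an error naming the offending line.
    """
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = {}
    for col in SAMPLE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric {col!r} value on line {line}")
        out[col] = vals.to_numpy(dtype=float)
    res = pd.DataFrame(out)
    if len(res) and res["stenosis_fraction"].max() > 1.5:
        warnings.warn(
            f"{path}: stenosis values look percent-coded; dividing by 100",
            UserWarning,
            stacklevel=2,
        )
        res["stenosis_fraction"] /= 100.0
    if len(res) and (res["stenosis_fraction"].min() < 0 or res["stenosis_fraction"].max() >= 1):
        raise ValueError(f"{path}: stenosis fractions must lie in [0, 1)")
    return res
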